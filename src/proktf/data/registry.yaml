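# Domain role registry: profile accessions -> functional roles, plus the
# architecture-defined family rules.  Edit freely; the loader validates.
#
# roles:   DBD | input | output | receiver | phosphotransfer | sigma_region |
#          odp_marker | other
# A DBD entry may carry dbd_subtype (the key family rules match on); a
# sigma_region entry carries its region tag (r2/r3/r4/s54_dbd/s54_core).
# families: dbd = any-of DBD subtypes; partners = all-of accessions.  A rule
# with partners but no dbd is an override: any DBD plus the partners places
# the protein in that family (LexA / Peptidase_S24).

precedence: [RR, SF, OCS, TR]

roles:
  # --- DNA-binding domains (transcription-factor qualifying) ---
  HTH_MerR:      {role: DBD, dbd_subtype: HTH_MerR}
  HTH_1:         {role: DBD, dbd_subtype: HTH_1}          # LysR-type
  HTH_LacI:      {role: DBD, dbd_subtype: HTH_LacI}
  HTH_LuxR:      {role: DBD, dbd_subtype: HTH_LuxR}       # GerE-type
  Trans_reg_C:   {role: DBD, dbd_subtype: Trans_reg_C}    # OmpR-type effector
  HTH_ArsR:      {role: DBD, dbd_subtype: HTH_ArsR}
  HTH_TetR:      {role: DBD, dbd_subtype: HTH_TetR}
  HTH_AraC:      {role: DBD, dbd_subtype: HTH_AraC}
  HTH_IclR:      {role: DBD, dbd_subtype: HTH_IclR}
  HTH_XRE:       {role: DBD, dbd_subtype: Xre}
  HTH_3:         {role: DBD, dbd_subtype: Xre}            # near-identical to HTH_XRE
  LexA_DNA_bin:  {role: DBD, dbd_subtype: LexA_DNA_bin}
  Mga:           {role: DBD, dbd_subtype: Mga}
  HTH_8:         {role: DBD, dbd_subtype: HTH_8}          # Fis-type
  HTH_Crp:       {role: DBD, dbd_subtype: HTH_Crp}
  GntR:          {role: DBD, dbd_subtype: GntR}
  MarR:          {role: DBD, dbd_subtype: MarR}
  HTH_DeoR:      {role: DBD, dbd_subtype: HTH_DeoR}
  AsnC_trans_reg: {role: DBD, dbd_subtype: AsnC_trans_reg} # Lrp/AsnC-type
  PadR:          {role: DBD, dbd_subtype: PadR}
  Fur:           {role: DBD, dbd_subtype: Fur}

  # --- sigma factor regions ---
  Sigma70_r2:    {role: sigma_region, sigma: r2}
  Sigma70_r3:    {role: sigma_region, sigma: r3}
  Sigma70_r4:    {role: sigma_region, sigma: r4}
  Sigma54_DBD:   {role: sigma_region, sigma: s54_dbd}
  Sigma54_CBD:   {role: sigma_region, sigma: s54_core}

  # --- receiver (phosphoacceptor) ---
  Response_reg:  {role: receiver}

  # --- sensory input / ligand binding ---
  PAS:           {role: input}
  GAF:           {role: input}
  B12-binding:   {role: input}
  Periplasmic_binding: {role: input}
  Peptidase_S24: {role: input}    # LexA autoprotease moiety
  FCD:           {role: input}
  Cache:         {role: input}

  # --- phosphotransfer (two-component kinase side) ---
  HisKA:         {role: phosphotransfer}
  HATPase_c:     {role: phosphotransfer}
  Hpt:           {role: phosphotransfer}

  # --- non-DNA-binding output ---
  GGDEF:         {role: output}
  EAL:           {role: output}

  # --- non-regulatory DNA binders (ODP markers) ---
  Transposase_mut: {role: odp_marker}
  Integrase_core:  {role: odp_marker}
  Phage_integrase: {role: odp_marker}
  DDE_Tnp_1:       {role: odp_marker}
  HNS:             {role: odp_marker}
  Bac_DNA_binding: {role: odp_marker}   # HU/IHF histone-like

aliases:
  # common synonyms and numeric accessions seen in hit tables
  REC: Response_reg
  CheY-like: Response_reg
  PF00072: Response_reg
  HTH_Xre: HTH_XRE
  TetR_N: HTH_TetR
  GerE: HTH_LuxR
  LacI: HTH_LacI
  Crp: HTH_Crp
  PF00717: Peptidase_S24
  pfam00717: Peptidase_S24
  pfam717: Peptidase_S24
  pfam4542: Sigma70_r2
  pfam04542: Sigma70_r2
  pfam4539: Sigma70_r3
  pfam04539: Sigma70_r3
  pfam4545: Sigma70_r4
  pfam04545: Sigma70_r4
  pfam4552: Sigma54_DBD
  pfam04552: Sigma54_DBD
  pfam4963: Sigma54_CBD
  pfam04963: Sigma54_CBD
  Sigma54_core: Sigma54_CBD
  Sigma70_r4_2: Sigma70_r4
  PF00376: HTH_MerR
  rve: Integrase_core

families:
  # override: any DBD accompanied by the autoprotease domain is a LexA
  - {name: LexA, partners: [Peptidase_S24], priority: 100}
  - {name: LexA, dbd: [LexA_DNA_bin], priority: 10}
  - {name: MerR, dbd: [HTH_MerR]}
  - {name: LysR, dbd: [HTH_1]}
  - {name: LacI, dbd: [HTH_LacI]}
  - {name: LuxR, dbd: [HTH_LuxR]}
  - {name: OmpR, dbd: [Trans_reg_C]}
  - {name: ArsR, dbd: [HTH_ArsR]}
  - {name: TetR, dbd: [HTH_TetR]}
  - {name: AraC, dbd: [HTH_AraC]}
  - {name: IclR, dbd: [HTH_IclR]}
  - {name: Xre, dbd: [Xre]}
  - {name: Mga, dbd: [Mga]}
  - {name: Fis, dbd: [HTH_8]}
  - {name: Crp, dbd: [HTH_Crp]}
  - {name: GntR, dbd: [GntR]}
  - {name: MarR, dbd: [MarR]}
  - {name: DeoR, dbd: [HTH_DeoR]}
  - {name: Lrp, dbd: [AsnC_trans_reg]}
  - {name: PadR, dbd: [PadR]}
  - {name: Fur, dbd: [Fur]}
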