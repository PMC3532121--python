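# proktf

Prediction and domain-architecture classification of prokaryotic
transcription factors (TFs) from annotated proteomes **and** from ORFeomes
reconstituted directly from replicon DNA.

Transcription factors are DNA-binding proteins that activate or repress
transcription. In prokaryotes they are recognised reliably from their
domain complement: a protein enters the analysis when it carries a
DNA-binding domain (DBD), a sigma-factor region, or a non-regulatory
DNA-binding marker, and its ordered set of significant profile matches —
its *architecture* — then determines everything else. `proktf` implements
that scheme as a scriptable, tested pipeline for microbiologists and
comparative genomicists who want consistent TF annotation across genomes,
including recovery of regulator genes missing from the deposited
annotation.

## The classification scheme

Profile matches (RPS-BLAST tabular or HMMER3 `--domtblout`) are kept when
**E ≤ 0.01** and the alignment covers **≥ 50%** of the profile length.
Filtered architectures are then classified hierarchically:

1. **TF vs ODP** — proteins whose only DNA-binding evidence is a
   transposase / integrase / histone-like marker are *Other DNA-binding
   Proteins*; any TF-qualifying DBD wins.
2. **Category** (precedence RR > SF > OCS > TR):
   * **RR** (response regulator): any CheY-like receiver domain;
   * **SF** (sigma factor): σ54 DNA-binding + core-binding domains →
     **RpoN**; σ70 regions 2 + 4 → **ECF**, plus region 3 → **RpoD**;
   * **OCS** (one-component system): sensory input domain + DBD, with no
     phosphotransfer domain;
   * **TR** (transcriptional regulator): the total residual.
3. **Family** — from the DBD with the lowest E-value (MerR, LysR, TetR,
   Xre, …), with two special rules: any DBD accompanied by a
   Peptidase_S24 autoprotease domain makes a **LexA**-family repressor,
   and the near-identical HTH_XRE / HTH_3 domains share the single family
   **Xre**.

Around every classified TF gene the pipeline also reports the gene
neighbourhood: consecutive genes chained while each intergenic gap stays
within 500 bp, tagged with COG letters, pseudogene flags and TF-neighbour
flags.

The whole rule set lives in an editable YAML registry
(`src/proktf/data/registry.yaml`); no rule is hard-coded.

## ORFeome reconstruction and "mispredicted" genes

Independently of the annotation, every valid ORF (start codon → first
in-frame stop, both strands, all six frames, ≥ 60 aa by default) is
enumerated and translated. ORFs that carry qualifying domain hits but
overlap no annotated same-strand CDS are reported as **mispredicted** TF
genes — unless they touch a feature annotated as a pseudogene, which is
never resurrected.

## Worked example

```bash
python examples/02_classify_architectures.py
```

```
11 raw hits (including 2 planted sub-threshold decoys)
5 DNA-binding proteins after filtering

protein      TF/ODP  category  family   signature
carA_like    TF      OCS       MerR     HTH_MerR+B12-binding
carQ_like    TF      SF        ECF      Sigma70_r2+Sigma70_r4
gacA_like    TF      RR        LuxR     Response_reg+HTH_LuxR
lexA_like    TF      OCS       LexA     HTH_XRE+Peptidase_S24
tnp_like     ODP     none      None     Transposase_mut
```

Five proteins with characteristic architectures are classified; the two
decoy hits (one failing the E-value cut-off, one the coverage floor) are
removed by the filter, and the Xre-domain protein is assigned to the LexA
family because of its Peptidase_S24 domain. The other scripts in
`examples/` demonstrate ORFeome scanning, mispredicted-gene recovery,
neighbourhood walking, and a full pipeline run with a self-benchmark.

A complete run is driven by a small YAML config:

```bash
proktf fixtures --seed 7 --out demo/      # synthetic genome bundle
proktf run --config demo/run.yaml         # ORFeome → scan → classify → context
```

which writes `tf_table.tsv`, `mispredicted.tsv`, `context.tsv`,
`summary.tsv`, FASTA exports and a `manifest.json` with input checksums,
parameters and counts. Reruns are byte-identical.

## Layout

* `src/proktf/orfeome.py` — six-frame ORF enumeration, mispredicted calls
* `src/proktf/domain_scan.py` — hit parsing, filtering, architectures
* `src/proktf/registry.py` + `data/registry.yaml` — the rule data
* `src/proktf/classify.py` — TF/ODP, categories, families
* `src/proktf/context.py` — gene-neighbourhood chaining
* `src/proktf/report.py`, `pipeline.py` — summaries, exports, orchestration
* `src/proktf/fixtures.py` — planted synthetic genomes with known truth
* `docs/methods.md` — model, parameters, design choices, limitations
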