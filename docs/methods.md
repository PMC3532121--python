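# Methods

This note documents the models and procedures implemented by `proktf`, the
parameters that matter, the numerical and design choices made where the
problem left room, what the synthetic-data generator does and does not
emulate, and the known limitations.

## ORFeome reconstitution

A *valid ORF* is a maximal reading frame: it begins at a start codon, ends
at the first in-frame stop codon, and is enumerated on both strands in all
six frames. Per (frame, stop) pair only the longest compatible ORF — the
earliest start since the previous in-frame stop — is reported by default;
`all_starts=True` emits nested starts as well. This is exhaustive
enumeration, not gene calling: there is no ribosome-binding-site scoring
and no coding-potential statistic, so the ORFeome deliberately
over-predicts and relies on the downstream domain filter for specificity.

Parameters:

* `start_codons` — default `{ATG, GTG, TTG}`, the standard initiators of
  the bacterial genetic code; `CTG` and `ATT` may be added.
* `min_aa_length` — default 60 aa (translated length, stop excluded), a
  conventional floor for prokaryotic protein-coding genes. Both defaults
  are configurable; recovery statistics shift with them, so runs record
  them in the manifest.

Conventions and numerics:

* All coordinates in records and files are 1-based inclusive on the
  forward strand (GenBank convention); half-open arithmetic exists only
  inside the scanner.
* Translation uses the bacterial code; the initiator translates as M
  whatever its codon. Codons containing `N` never act as start or stop
  and translate as `X`; any other letter rejects the input.
* The scan runs on a base-5 numeric encoding with vectorised codon
  classification, so whole replicons scan in milliseconds.
* Circular replicons are scanned on the doubled sequence; an ORF is kept
  when its 5′ scan coordinate lies in the first period, origin-spanning
  ORFs are reported once with `wraps_origin` set (and `end < start` after
  normalisation), and ORFs as long as the replicon are dropped. A
  consequence of the doubling policy is that the "previous stop" context
  near the origin is that of the doubled string; in practice this only
  affects replicons with a stop-free frame across the whole period.

### Mispredicted genes

An ORF with qualifying domain hits is *mispredicted* when no annotated
same-strand CDS covers more than `overlap_threshold` (default 0.1) of its
length, and it overlaps no pseudogene feature at all, on either strand.
The fractional same-strand overlap is a conservative, reproducible
operationalisation of "not present in the proteome"; pseudogene exclusion
is absolute because annotators marked those loci as decayed on purpose.

## Domain significance filter

A profile match survives when `E ≤ 0.01` **and**
`aligned_profile_length / profile_length ≥ 0.5`. Both boundaries are
inclusive — a hit at exactly (0.01, 0.50) passes — and coverage is
measured over the profile (domain model), not the query protein, so short
proteins can still show full-coverage domains. Accessions unknown to the
registry survive filtering with role `other`; registry gaps therefore
degrade into countable `unclassified` families rather than crashes.

Overlapping hits on one protein are reduced before classification: among
hits overlapping by more than 50% of the shorter interval, the lowest
E-value wins (ties: higher bitscore, then lexicographically smaller
accession), applied greedily in rank order. Overlap reduction is a policy
of this implementation, isolated in `resolve_overlaps` and switchable off
(`keep_overlaps`), because reasonable pipelines differ here.

## Classification

Classification is a pure function of the architecture and the registry.

* **Gate.** Any hit with role `DBD`, `sigma_region` or `odp_marker`
  admits the protein.
* **TF vs ODP.** ODP iff the DNA-binding evidence is exclusively
  `odp_marker` accessions. For mixed architectures (e.g. integrase +
  regulatory HTH) the TF-qualifying DBD wins: the ODP bin is for
  *non-regulatory* DNA binders, so any regulatory domain disqualifies it.
* **Category precedence** is a registry setting, default
  `RR > SF > OCS > TR`. The receiver domain is treated as decisive — a
  receiver plus sigma regions is still an RR — because phosphorelay
  control is the defining property of the response-regulator class, and
  TR is the explicit residual. Within SF typing, the σ54 rule is checked
  before the σ70 rules; architectures carrying both (not observed in
  practice) type as RpoN. σ70 region 3 without regions 2 + 4 does not
  make a sigma factor. An input domain alongside the DBD makes an OCS
  only when no phosphotransfer domain is present; with one, the protein
  reads as the kinase side of a two-component system and falls to TR.
* **Families.** Override rules run first: any DBD plus all partner
  domains of an override (shipped: Peptidase_S24 → LexA) assigns that
  family whatever the DBD identities or E-values. Otherwise the DBD hit
  with the lowest E-value (ties: bitscore, then accession) selects the
  family rule listing its subtype. HTH_XRE and HTH_3 carry the same
  subtype and merge into Xre. Sigma factors use their subfamily as the
  family. No match yields `unclassified`, never an error.

The shipped registry encodes the families that can be defined from
well-known DBD subtypes (MerR, LysR, LacI, LuxR, OmpR, ArsR, TetR, AraC,
IclR, Xre, LexA, Mga, Fis, Crp, GntR, MarR, DeoR, Lrp, PadR, Fur) plus
the sigma subfamilies. It is deliberately smaller than an exhaustive
family catalogue; the YAML schema (roles, subtypes, aliases, families,
precedence) is the extension mechanism, and receiver-only proteins
without any DBD are excluded by the gate rather than counted as RRs.

## Gene neighbourhood

From each TF the walk proceeds outward in both directions, admitting the
next gene while its intergenic gap to the previous gene in the chain is
at most `window` (default 500 bp, inclusive; overlaps floor at 0). The
chaining is transitive — operon-like blocks, matching the purpose of
flagging putative regulation regions — with a `max_neighbours` safety cap
(default 10 per side). Strand is recorded but does not break chains
unless `same_strand` is set, since no strand rule is part of the window
definition. On circular replicons the walk wraps across the origin.

## Reporting and evaluation

Genome summaries enforce their own invariants on every run
(TF + ODP = total; TR + OCS + RR + SF = TF; RpoN + RpoD + ECF = SF). The
DBD percentage of the proteome is `100 × total / proteome_size` rounded
to one decimal. Benchmark evaluation uses sensitivity `TP/(TP+FN)` and
specificity `TN/(TN+FP)` over an explicit gene universe; undefined ratios
(zero denominators) are reported as `None` and serialised as empty cells,
never as 0. Every pipeline run writes a manifest (input SHA-256s,
parameters, versions, counts) sufficient to reproduce the outputs
bit-identically.

## Synthetic-data generator

`fixtures.make_genome` plants a replicon whose genes are genuine ORFs at
recorded coordinates: each begins with ATG, contains no internal stop,
ends at a stop codon, and an in-frame stop guard is written immediately
5′ of the start so the scanner recovers exactly the planted interval. The
hit table realises each requested classification, includes hits placed
exactly on the (0.01, 0.50) filter boundaries, and sprinkles
sub-threshold decoys whose retention would flip a call. Mispredicted
genes are present in the DNA but absent from the annotation; pseudogene
scenarios additionally cover the hidden gene with a pseudogene feature.
Intergenic gaps are drawn mostly below and occasionally above the 500 bp
window so context chains both form and break. All randomness flows from
one seed; identical seeds give byte-identical bundles.

What the generator does **not** emulate: real domain sequences (hits are
tabulated, not found by an actual profile search), codon usage,
overlapping genes, operonic structure beyond gap distances, sequencing
artefacts, or annotation errors other than plain omission. Passing the
planted-truth tests therefore demonstrates that the *logic* downstream of
the profile search is exact, not that any particular profile library
would reproduce a published TF census; applying the pipeline to a real
genome requires running RPS-BLAST or hmmscan externally and feeding the
table in.

## Verification problem sizes

The test suite and `scripts/acceptance.py` verify the scan against an
independent brute-force six-frame enumerator on ~1,000 random replicons
of 0.3–30 kb at 25–75% GC, the category rules over all 2^6 role-presence
combinations, pipeline closure on dozens of seeded planted genomes
(10–20 genes each), neighbourhood chaining on 200 random layouts, and the
evaluation arithmetic on 1,000 random set triples — sizes at which the
brute-force oracles are themselves trivially auditable.

## Known limitations

* Classification quality on real data is bounded by the profile library
  and registry coverage; novel DBDs without profiles are invisible.
* The family catalogue is a maintained subset, not an exhaustive
  reconstruction of any particular database release.
* The ORFeome stage trades precision for recall by design; its output is
  only as specific as the domain filter that gates it.
* Overlap resolution and category precedence are documented policies, not
  biological facts; both are switchable/configurable where they matter.
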