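"""End-to-end run on a synthetic genome, with a self-benchmark.

Generates a genome bundle (GenBank + hit tables + COG table + run config),
executes the whole pipeline, prints the genome summary, and scores the
predictions against the generator's planted truth using the standard
sensitivity / specificity definitions.
"""

import tempfile
from pathlib import Path

from proktf import evaluate, make_genome, run_pipeline

pg = make_genome(
    {"TR": 6, "OCS": 4, "RR": 3, "SF-ECF": 2, "SF-RpoD": 1, "ODP": 2},
    n_mispredicted=1,
    n_pseudogenes=1,
    n_fillers=6,
    seed=3,
)

with tempfile.TemporaryDirectory() as tmp:
    result = run_pipeline(pg.write(Path(tmp)))
    s = result.summary
    print(f"replicon(s): {', '.join(s.replicon_ids)}")
    print(f"proteome size          {s.proteome_size}")
    print(f"DBD proteins           {s.total_dbd} ({s.pct_dbd_of_proteome}% of proteome)")
    print(f"  transcription factors {s.tf_count}")
    print(f"  other DNA binders     {s.odp_count}")
    for cat, n in s.category_counts.items():
        print(f"  {cat:4s} {n}")
    print(f"  sigma subfamilies     {s.sf_subfamily_counts}")
    print(f"  families              {s.family_counts}")
    print(f"  mispredicted          {s.mispredicted_count}")

    truth = pg.truth
    universe = {g.protein_id for g in pg.genes}
    reference = set(truth[truth.in_output & (truth.dbd_or_odp == "TF")].protein_id)
    predicted = {r.protein_id for r in result.records if r.dbd_or_odp == "TF"}
    ev = evaluate(predicted, reference, universe)
    print(f"\nself-benchmark vs planted truth:")
    print(f"  sensitivity {ev.sensitivity:.3f}  specificity {ev.specificity:.3f}")
    print(f"outputs written under {result.out_dir}")
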