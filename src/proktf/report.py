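"""Per-genome summaries, benchmark evaluation and tabular/FASTA exports."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import ProktfError
from .classify import TFRecord

__all__ = [
    "GenomeSummary",
    "EvaluationResult",
    "summarize",
    "evaluate",
    "export",
    "import_tsv",
    "TF_TABLE_COLUMNS",
]


@dataclass
class GenomeSummary:
    """Counts of classified DNA-binding proteins for one genome/run."""

    replicon_ids: tuple[str, ...]
    total_dbd: int
    tf_count: int
    odp_count: int
    category_counts: dict[str, int]  # TR / OCS / RR / SF
    sf_subfamily_counts: dict[str, int]  # RpoN / RpoD / ECF
    family_counts: dict[str, int]
    mispredicted_count: int
    proteome_size: int
    pct_dbd_of_proteome: float | None  # rounded to 1 decimal; None if size 0

    def check(self) -> None:
        if self.tf_count + self.odp_count != self.total_dbd:
            raise ProktfError("summary invariant violated: TF + ODP != total")
        if sum(self.category_counts.values()) != self.tf_count:
            raise ProktfError("summary invariant violated: categories != TF count")
        if sum(self.sf_subfamily_counts.values()) != self.category_counts.get("SF", 0):
            raise ProktfError("summary invariant violated: SF subfamilies != SF count")
        if self.mispredicted_count > self.total_dbd:
            raise ProktfError("summary invariant violated: mispredicted > total")


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion-matrix comparison of predictions against a reference set."""

    true_positives: int
    false_negatives: int
    false_positives: int
    true_negatives: int
    sensitivity: float | None  # TP / (TP + FN); None when undefined
    specificity: float | None  # TN / (TN + FP); None when undefined


def summarize(
    tf_records: Sequence[TFRecord],
    proteome_size: int,
    replicon_ids: Sequence[str] = (),
) -> GenomeSummary:
    """Aggregate classified records into the genome-page style counts.

    The DBD-protein percentage is 100 x total / proteome_size, rounded to one
    decimal (undefined when the proteome size is zero).
    """
    tfs = [r for r in tf_records if r.dbd_or_odp == "TF"]
    odps = [r for r in tf_records if r.dbd_or_odp == "ODP"]
    cats = Counter(r.category for r in tfs)
    sfs = Counter(r.sf_subfamily for r in tfs if r.category == "SF")
    fams = Counter(r.family for r in tfs if r.family)
    total = len(tfs) + len(odps)
    pct = round(100.0 * total / proteome_size, 1) if proteome_size else None
    summary = GenomeSummary(
        replicon_ids=tuple(replicon_ids),
        total_dbd=total,
        tf_count=len(tfs),
        odp_count=len(odps),
        category_counts={c: cats.get(c, 0) for c in ("TR", "OCS", "RR", "SF")},
        sf_subfamily_counts={s: sfs.get(s, 0) for s in ("RpoN", "RpoD", "ECF")},
        family_counts=dict(sorted(fams.items())),
        mispredicted_count=sum(1 for r in tf_records if r.mispredicted),
        proteome_size=proteome_size,
        pct_dbd_of_proteome=pct,
    )
    summary.check()
    return summary


def evaluate(
    predicted: Iterable[str], reference_positive: Iterable[str], universe: Iterable[str]
) -> EvaluationResult:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) over a gene universe.

    Undefined ratios (zero denominators) are reported as None, never as 0.
    """
    pred, ref, uni = set(predicted), set(reference_positive), set(universe)
    if not ref <= uni or not pred <= uni:
        raise ProktfError("predicted and reference sets must lie in the universe")
    tp = len(pred & ref)
    fn = len(ref - pred)
    fp = len(pred - ref)
    tn = len(uni - pred - ref)
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return EvaluationResult(tp, fn, fp, tn, sens, spec)


TF_TABLE_COLUMNS = (
    "protein_id",
    "locus_tag",
    "dbd_or_odp",
    "category",
    "sf_subfamily",
    "family",
    "signature",
    "dbd_count",
    "distinct_dbd_count",
    "mispredicted",
    "provenance",
)


def records_frame(tf_records: Sequence[TFRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "locus_tag": r.locus_tag or "",
                "dbd_or_odp": r.dbd_or_odp,
                "category": r.category,
                "sf_subfamily": r.sf_subfamily,
                "family": r.family if r.family is not None else "",
                "signature": r.architecture.signature,
                "dbd_count": r.architecture.dbd_count,
                "distinct_dbd_count": r.architecture.distinct_dbd_count,
                "mispredicted": r.mispredicted,
                "provenance": r.provenance,
            }
            for r in tf_records
        ],
        columns=list(TF_TABLE_COLUMNS),
    )


def _fasta_header(r: TFRecord) -> str:
    locus = r.locus_tag or r.protein_id
    return (
        f"{locus}|{r.dbd_or_odp}|{r.category}|{r.family or 'NA'}|{r.provenance}"
        f"{'|mispredicted' if r.mispredicted else ''}"
    )


def export(
    tf_records: Sequence[TFRecord],
    fmt: str,
    path: str | Path,
) -> Path:
    """Write the classification in one of the download formats.

    ``tsv`` is the canonical, round-trippable table; ``fasta_aa`` and
    ``fasta_nt`` need records carrying sequences and fail loudly naming the
    offenders otherwise; ``xlsx_csv`` is the spreadsheet-oriented CSV twin of
    the TSV (written as a native workbook instead when the path ends in
    ``.xlsx`` and openpyxl is available).
    """
    path = Path(path)
    if fmt == "tsv":
        records_frame(tf_records).to_csv(path, sep="\t", index=False)
    elif fmt == "xlsx_csv":
        frame = records_frame(tf_records)
        if path.suffix == ".xlsx":
            try:
                frame.to_excel(path, index=False)
            except ImportError:
                raise ProktfError("native workbook export needs openpyxl")
        else:
            frame.to_csv(path, index=False)
    elif fmt in ("fasta_aa", "fasta_nt"):
        attr = "aa_sequence" if fmt == "fasta_aa" else "nt_sequence"
        missing = [r.protein_id for r in tf_records if not getattr(r, attr)]
        if missing:
            raise ProktfError(
                f"{fmt} export requires sequences; missing for {', '.join(missing)}"
            )
        SeqIO.write(
            [
                SeqRecord(Seq(getattr(r, attr)), id=_fasta_header(r), description="")
                for r in tf_records
            ],
            str(path),
            "fasta",
        )
    else:
        raise ProktfError(f"unknown export format {fmt!r}")
    return path


def import_tsv(path: str | Path) -> pd.DataFrame:
    """Re-read an exported TSV with stable dtypes (round-trip partner)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("protein_id", "locus_tag", "family", "signature")},
        keep_default_na=False,
    )
    missing = set(TF_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ProktfError(f"{path}: missing columns {sorted(missing)}")
    return frame
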