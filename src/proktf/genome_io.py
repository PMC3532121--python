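"""Reading replicons and writing ORFeome / protein files.

GenBank flat files are the primary annotated input (CDS features with
``/locus_tag``, ``/protein_id`` and ``/pseudo`` qualifiers); bare replicons
come in as FASTA, and GFF3 + FASTA is accepted as an annotation alternative.
All parsing goes through Biopython / gffutils; this module only maps the
results onto the package's coordinate conventions (1-based inclusive,
forward strand).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._util import ProktfError, translate_bacterial
from .orfeome import GeneFeature, OrfRecord, Replicon

__all__ = [
    "read_replicons",
    "read_replicons_gff3",
    "write_orfeome_fasta",
    "write_orfeome_table",
    "write_genbank",
    "read_cog_table",
    "feature_protein",
]


def _features_from_seqrecord(rec: SeqRecord) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    counter = 0
    for f in rec.features:
        if f.type not in ("CDS", "gene"):
            continue
        pseudo = "pseudo" in f.qualifiers or "pseudogene" in f.qualifiers
        if f.type == "gene" and not pseudo:
            continue  # plain gene features duplicate their CDS
        counter += 1
        tag = f.qualifiers.get("locus_tag", [f"feature_{counter}"])[0]
        if tag in seen:
            continue  # gene + CDS pair for the same locus
        seen.add(tag)
        product = f.qualifiers.get("protein_id", [None])[0]
        feats.append(
            GeneFeature(
                locus_tag=tag,
                start=int(f.location.start) + 1,
                end=int(f.location.end),
                strand="-" if f.location.strand == -1 else "+",
                kind="pseudogene" if pseudo else ("CDS" if f.type == "CDS" else "other"),
                product_id=product,
            )
        )
    return feats


def read_replicons(path: str | Path, fmt: str | None = None) -> list[Replicon]:
    """Load replicons from FASTA or GenBank (auto-detected by extension)."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
            fmt = "genbank"
        elif suffix in (".fa", ".fna", ".fasta"):
            fmt = "fasta"
        else:
            raise ProktfError(f"cannot infer format of {path}; pass fmt=")
    out: list[Replicon] = []
    for rec in SeqIO.parse(str(path), fmt):
        topology = "linear"
        if fmt == "genbank":
            topology = rec.annotations.get("topology", "linear")
        out.append(
            Replicon(
                id=rec.id,
                sequence=str(rec.seq),
                topology=topology if topology in ("linear", "circular") else "linear",
                features=_features_from_seqrecord(rec) if fmt == "genbank" else [],
            )
        )
    if not out:
        raise ProktfError(f"no sequences found in {path}")
    return out


def read_replicons_gff3(gff_path: str | Path, fasta_path: str | Path) -> list[Replicon]:
    """Load replicons from a GFF3 annotation plus a FASTA of the sequences."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_seqid: dict[str, list[GeneFeature]] = {}
    for f in db.all_features():
        if f.featuretype not in ("CDS", "pseudogene", "gene"):
            continue
        pseudo = f.featuretype == "pseudogene" or f.attributes.get("pseudo") or (
            "pseudogene" in (f.attributes.get("gene_biotype") or [])
        )
        if f.featuretype == "gene" and not pseudo:
            continue
        tag = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [f.id])[0]
        product = (f.attributes.get("protein_id") or [None])[0]
        by_seqid.setdefault(f.seqid, []).append(
            GeneFeature(
                locus_tag=tag,
                start=f.start,
                end=f.end,
                strand="-" if f.strand == "-" else "+",
                kind="pseudogene" if pseudo else "CDS",
                product_id=product,
            )
        )
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        feats = by_seqid.get(rec.id, [])
        seen: set[str] = set()
        uniq = [f for f in feats if not (f.locus_tag in seen or seen.add(f.locus_tag))]
        out.append(Replicon(id=rec.id, sequence=str(rec.seq), features=uniq))
    if not out:
        raise ProktfError(f"no sequences found in {fasta_path}")
    return out


def feature_protein(replicon: Replicon, feature: GeneFeature) -> str:
    """Translate an annotated CDS from the replicon sequence (table 11)."""
    nt = replicon.sequence[feature.start - 1 : feature.end]
    if feature.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    return translate_bacterial(nt)


def orf_header(orf: OrfRecord) -> str:
    return (
        f"{orf.orf_id}|{orf.replicon_id}|{orf.start}..{orf.end}|{orf.strand}"
        f"|{orf.provenance}"
    )


def write_orfeome_fasta(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(o.translation), id=orf_header(o), description="") for o in orfs
    ]
    SeqIO.write(records, str(path), "fasta")


ORFEOME_COLUMNS = (
    "orf_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "frame",
    "nt_length",
    "aa_length",
    "provenance",
    "wraps_origin",
    "mispredicted",
)


def write_orfeome_table(orfs: Sequence[OrfRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "orf_id": o.orf_id,
                "replicon_id": o.replicon_id,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "frame": o.frame,
                "nt_length": o.nt_length,
                "aa_length": o.aa_length,
                "provenance": o.provenance,
                "wraps_origin": o.wraps_origin,
                "mispredicted": o.mispredicted,
            }
            for o in orfs
        ],
        columns=list(ORFEOME_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def write_genbank(replicon: Replicon, path: str | Path) -> None:
    """Serialise a replicon with its features as a GenBank flat file."""
    rec = SeqRecord(
        Seq(replicon.sequence),
        id=replicon.id,
        name=replicon.id[:16],
        description="synthetic replicon",
        annotations={"molecule_type": "DNA", "topology": replicon.topology},
    )
    for f in replicon.features:
        qualifiers: dict = {"locus_tag": [f.locus_tag]}
        if f.product_id:
            qualifiers["protein_id"] = [f.product_id]
        ftype = "CDS"
        if f.kind == "pseudogene":
            ftype = "gene"
            qualifiers["pseudo"] = [""]
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1),
                type=ftype,
                qualifiers=qualifiers,
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def read_cog_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: protein/locus id -> COG functional category letter(s)."""
    cogs: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ProktfError(f"{path}: malformed COG row {line!r}")
            cogs[parts[0]] = parts[1]
    return cogs
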