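"""Synthetic replicons, annotations and domain-hit tables with planted truth.

Every stage of the pipeline is testable without downloading a genome or a
profile database: this module writes a replicon whose genes are real ORFs at
recorded coordinates, an annotation that deliberately omits some of them
(the "mispredicted" genes the ORFeome stage must recover), pseudogene
features overlapping others (which must *not* be recovered), and a domain-hit
table whose accessions, E-values and coverages force a requested
classification for every protein — including hits placed exactly on the
E = 0.01 / coverage = 0.50 boundaries and sub-threshold decoys the filter
must reject.

Synthetic proteins do not resemble real domain sequences; hit tables are
generated directly, because everything under test sits downstream of the
profile search.  All randomness flows from one seed: the same seed gives a
byte-identical genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import ProktfError, revcomp
from .domain_scan import RawHit
from .genome_io import write_genbank
from .orfeome import GeneFeature, Replicon, make_orf_id
from .registry import DomainRoleRegistry, load_default_registry

__all__ = ["PlantedGene", "PlantedGenome", "make_genome", "make_hit_table", "write_hit_tsv"]

# codons that are neither stops nor (to keep planted starts unambiguous
# irrelevant) anything special; sampled for gene bodies
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOPS = ("TAA", "TAG", "TGA")

# architecture menu: per category-key, (accessions in order, expected family)
_MENU: dict[str, list[tuple[list[str], str | None]]] = {
    "TR": [
        (["HTH_TetR"], "TetR"),
        (["HTH_ArsR"], "ArsR"),
        (["MarR"], "MarR"),
        (["HTH_XRE"], "Xre"),
        (["HTH_3"], "Xre"),
        (["Fur"], "Fur"),
        # input + DBD + phosphotransfer: the kinase-like architecture that
        # must be denied the one-component call and fall through to TR
        (["PAS", "HTH_LuxR", "HisKA"], "LuxR"),
    ],
    "OCS": [
        (["HTH_MerR", "B12-binding"], "MerR"),
        (["HTH_LacI", "Periplasmic_binding"], "LacI"),
        (["PAS", "HTH_AraC"], "AraC"),
        (["LexA_DNA_bin", "Peptidase_S24"], "LexA"),
        (["HTH_XRE", "Peptidase_S24"], "LexA"),
        (["GAF", "HTH_1"], "LysR"),
    ],
    "RR": [
        (["Response_reg", "HTH_LuxR"], "LuxR"),
        (["Response_reg", "Trans_reg_C"], "OmpR"),
        (["Response_reg", "HTH_8"], "Fis"),
    ],
    "SF-ECF": [(["Sigma70_r2", "Sigma70_r4"], "ECF")],
    "SF-RpoD": [(["Sigma70_r2", "Sigma70_r3", "Sigma70_r4"], "RpoD")],
    "SF-RpoN": [(["Sigma54_CBD", "Sigma54_DBD"], "RpoN")],
    "ODP": [
        (["Transposase_mut"], None),
        (["Integrase_core"], None),
        (["HNS"], None),
    ],
}

#: accessions used as sub-threshold decoys; kept they would flip a call
_DECOY_ACCESSIONS = (
    "Response_reg",
    "Sigma70_r2",
    "HisKA",
    "Peptidase_S24",
    "HTH_MerR",
    "Transposase_mut",
)


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one planted gene."""

    protein_id: str  # locus tag (annotated) or ORF id (omitted genes)
    start: int
    end: int
    strand: str
    aa_length: int
    role: str  # annotated | mispredicted | pseudogene_overlap | filler
    dbd_or_odp: str | None  # TF | ODP | None for fillers
    category: str  # TR/OCS/RR/SF/none
    sf_subfamily: str
    family: str | None
    accessions: tuple[str, ...]


@dataclass
class PlantedGenome:
    """A synthetic replicon bundle whose expected pipeline output is known."""

    replicon: Replicon
    genes: list[PlantedGene]
    proteome_hits: list[RawHit]
    orfeome_hits: list[RawHit]
    decoy_keys: list[tuple[str, str]]  # (protein_id, accession) planted sub-threshold
    cogs: dict[str, str]
    seed: int

    @property
    def truth(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            if g.dbd_or_odp is None:
                continue
            expected = g.role in ("annotated", "mispredicted")
            rows.append(
                {
                    "protein_id": g.protein_id,
                    "dbd_or_odp": g.dbd_or_odp,
                    "category": g.category,
                    "sf_subfamily": g.sf_subfamily,
                    "family": g.family or "",
                    "mispredicted": g.role == "mispredicted",
                    "provenance": "annotated" if g.role == "annotated" else "orfeome",
                    "in_output": expected,
                }
            )
        return pd.DataFrame(rows).sort_values("protein_id").reset_index(drop=True)

    def write(self, out_dir: str | Path) -> Path:
        """Emit genome.gbk, hit TSVs, truth.tsv, cogs.tsv and a run config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genbank(self.replicon, out / "genome.gbk")
        write_hit_tsv(self.proteome_hits, out / "proteome_hits.tsv")
        write_hit_tsv(self.orfeome_hits, out / "orfeome_hits.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "cogs.tsv", "w") as fh:
            for k in sorted(self.cogs):
                fh.write(f"{k}\t{self.cogs[k]}\n")
        config = {
            "genome": str(out / "genome.gbk"),
            "proteome_hits": {"path": str(out / "proteome_hits.tsv"), "dialect": "rpsblast_tab"},
            "orfeome_hits": {"path": str(out / "orfeome_hits.tsv"), "dialect": "rpsblast_tab"},
            "cogs": str(out / "cogs.tsv"),
            "out_dir": str(out / "results"),
        }
        with open(out / "run.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        return out / "run.yaml"


def _gene_hits(
    rng: np.random.Generator,
    protein_id: str,
    accessions: Sequence[str],
    aa_length_min: int,
    boundary: bool,
) -> tuple[list[RawHit], int]:
    """Hits realising one signature; returns hits and the protein length."""
    hits: list[RawHit] = []
    pos = int(rng.integers(2, 10))
    for i, acc in enumerate(accessions):
        width = int(rng.integers(40, 61))
        total = int(rng.integers(60, 121))
        if boundary and i == 0:
            evalue, total, aligned = 0.01, 100, 50  # exactly on both boundaries
        else:
            evalue = float(10.0 ** rng.uniform(-25, -5))
            aligned = int(np.ceil(rng.uniform(0.55, 0.98) * total))
        hits.append(
            RawHit(
                protein_id=protein_id,
                profile_accession=acc,
                evalue=evalue,
                query_start=pos,
                query_end=pos + width - 1,
                profile_aligned_length=aligned,
                profile_total_length=total,
                bitscore=float(np.round(rng.uniform(40, 300), 1)),
            )
        )
        pos += width + int(rng.integers(5, 20))
    aa_len = max(aa_length_min, pos + int(rng.integers(5, 30)))
    return hits, aa_len


def _decoy_hit(rng: np.random.Generator, protein_id: str, aa_len: int) -> RawHit:
    acc = str(rng.choice(_DECOY_ACCESSIONS))
    if rng.random() < 0.5:  # fails the E-value cut-off
        evalue, cov = float(rng.uniform(0.02, 5.0)), float(rng.uniform(0.6, 0.95))
    else:  # fails the coverage floor
        evalue, cov = float(10.0 ** rng.uniform(-20, -5)), float(rng.uniform(0.10, 0.45))
    total = 100
    start = int(rng.integers(1, max(2, aa_len - 40)))
    return RawHit(
        protein_id=protein_id,
        profile_accession=acc,
        evalue=evalue,
        query_start=start,
        query_end=start + 39,
        profile_aligned_length=max(1, int(round(cov * total))),
        profile_total_length=total,
        bitscore=float(np.round(rng.uniform(5, 40), 1)),
    )


def make_hit_table(
    architectures: Sequence[tuple[str, Sequence[str]]],
    *,
    n_decoys: int = 0,
    seed: int = 0,
    boundary_first: bool = False,
) -> list[RawHit]:
    """Hits realising the requested (protein_id, accession list) signatures.

    ``n_decoys`` extra sub-threshold hits (E > 0.01 or coverage < 0.5) are
    sprinkled over random proteins; ``boundary_first`` puts the very first
    hit exactly on the E = 0.01 / coverage = 0.50 boundary.
    """
    rng = np.random.default_rng(seed)
    hits: list[RawHit] = []
    lengths: dict[str, int] = {}
    for i, (pid, accs) in enumerate(architectures):
        gh, aa_len = _gene_hits(rng, pid, accs, 60, boundary_first and i == 0)
        hits.extend(gh)
        lengths[pid] = aa_len
    pids = [pid for pid, _ in architectures]
    for _ in range(n_decoys):
        pid = str(rng.choice(pids))
        hits.append(_decoy_hit(rng, pid, lengths[pid]))
    return hits


def _category_fields(key: str) -> tuple[str, str, str]:
    """category-key -> (dbd_or_odp, category, sf_subfamily)."""
    if key == "ODP":
        return "ODP", "none", "none"
    if key.startswith("SF-"):
        return "TF", "SF", key.split("-", 1)[1]
    return "TF", key, "none"


def make_genome(
    composition: Mapping[str, int],
    n_mispredicted: int = 0,
    n_pseudogenes: int = 0,
    *,
    n_fillers: int = 3,
    seed: int = 0,
    replicon_id: str | None = None,
    registry: DomainRoleRegistry | None = None,
) -> PlantedGenome:
    """Plant a replicon realising ``composition`` with known truth.

    ``composition`` maps category keys (``TR``, ``OCS``, ``RR``, ``SF-ECF``,
    ``SF-RpoD``, ``SF-RpoN``, ``ODP``) to annotated-gene counts.
    ``n_mispredicted`` extra TF genes are written into the DNA but left out
    of the annotation; ``n_pseudogenes`` more are likewise omitted but
    covered by a pseudogene feature, so the pipeline must refuse to recover
    them.  Fillers are ordinary genes without qualifying domains.

    Each planted gene is a genuine ORF: it begins with ATG, contains no
    internal stop, ends at a stop codon, and an in-frame stop guard is
    written immediately 5' of the start so the six-frame scan recovers the
    planted interval exactly.
    """
    registry = registry or load_default_registry()
    for key in composition:
        if key not in _MENU:
            raise ProktfError(f"unknown category key {key!r}")
    rng = np.random.default_rng(seed)
    rid = replicon_id or f"SYN{seed:05d}"

    # plan the gene list
    plans: list[dict] = []  # accessions/family/key/role
    for key in sorted(composition):
        for _ in range(composition[key]):
            accs, family = _MENU[key][int(rng.integers(len(_MENU[key])))]
            plans.append({"key": key, "accs": accs, "family": family, "role": "annotated"})
    tf_keys = [k for k in sorted(composition) if k != "ODP" and composition[k] > 0] or ["TR"]
    for _ in range(n_mispredicted):
        key = tf_keys[int(rng.integers(len(tf_keys)))]
        accs, family = _MENU[key][int(rng.integers(len(_MENU[key])))]
        plans.append({"key": key, "accs": accs, "family": family, "role": "mispredicted"})
    for _ in range(n_pseudogenes):
        key = tf_keys[int(rng.integers(len(tf_keys)))]
        accs, family = _MENU[key][int(rng.integers(len(_MENU[key])))]
        plans.append({"key": key, "accs": accs, "family": family, "role": "pseudogene_overlap"})
    for _ in range(n_fillers):
        plans.append({"key": None, "accs": [], "family": None, "role": "filler"})
    order = rng.permutation(len(plans))
    plans = [plans[i] for i in order]

    # realise hit tables and lengths, then lay genes on the replicon
    chunks: list[str] = []
    cursor = 0  # 0-based length so far
    genes: list[PlantedGene] = []
    features: list[GeneFeature] = []
    proteome_hits: list[RawHit] = []
    orfeome_hits: list[RawHit] = []
    cogs: dict[str, str] = {}
    boundary_done = False
    n_annot = 0

    def spacer(length: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=length))

    for i, plan in enumerate(plans):
        gap = int(rng.integers(620, 900)) if rng.random() < 0.25 else int(rng.integers(60, 450))
        strand = "+" if rng.random() < 0.5 else "-"
        if plan["role"] == "filler":
            aa_len = int(rng.integers(60, 160))
            hits: list[RawHit] = []
        else:
            # protein id assigned after coordinates are known for omitted genes
            hits, aa_len = _gene_hits(
                rng, "PENDING", plan["accs"], 60, not boundary_done and plan["role"] == "annotated"
            )
            if hits and not boundary_done and plan["role"] == "annotated":
                boundary_done = True
        body = "".join(
            _SENSE_CODONS[j] for j in rng.integers(0, len(_SENSE_CODONS), size=aa_len - 1)
        )
        coding = "ATG" + body + _STOPS[int(rng.integers(3))]
        gene_nt = coding if strand == "+" else revcomp(coding)
        # stop guard immediately 5' of the start, in frame
        guard = "TAA" if strand == "+" else ""
        tail_guard = "" if strand == "+" else "TTA"
        pre = spacer(gap - len(guard) - 3) + guard if strand == "+" else spacer(gap - 3)
        chunks.append(pre)
        cursor += len(pre)
        start1 = cursor + 1
        chunks.append(gene_nt)
        cursor += len(gene_nt)
        end1 = cursor
        if tail_guard:
            chunks.append(tail_guard)
            cursor += len(tail_guard)

        if plan["role"] == "annotated" or plan["role"] == "filler":
            n_annot += 1
            pid = f"PTF_{n_annot:04d}"
            features.append(
                GeneFeature(locus_tag=pid, start=start1, end=end1, strand=strand, kind="CDS")
            )
        else:
            pid = make_orf_id(rid, start1, end1, strand)
            if plan["role"] == "pseudogene_overlap":
                features.append(
                    GeneFeature(
                        locus_tag=f"PSG_{i:04d}",
                        start=max(1, start1 + int(rng.integers(0, 30))),
                        end=end1 - int(rng.integers(0, 30)),
                        strand=strand,
                        kind="pseudogene",
                    )
                )
        if plan["role"] == "filler":
            cogs[pid] = str(rng.choice(list("CEGHIJKLMNOPQTUV")))
        else:
            rekeyed = [
                RawHit(
                    protein_id=pid,
                    profile_accession=h.profile_accession,
                    evalue=h.evalue,
                    query_start=h.query_start,
                    query_end=h.query_end,
                    profile_aligned_length=h.profile_aligned_length,
                    profile_total_length=h.profile_total_length,
                    bitscore=h.bitscore,
                )
                for h in hits
            ]
            (proteome_hits if plan["role"] == "annotated" else orfeome_hits).extend(rekeyed)
        dbd_or_odp, category, sf_sub = (
            (None, "none", "none") if plan["role"] == "filler" else _category_fields(plan["key"])
        )
        genes.append(
            PlantedGene(
                protein_id=pid,
                start=start1,
                end=end1,
                strand=strand,
                aa_length=aa_len,
                role=plan["role"],
                dbd_or_odp=dbd_or_odp,
                category=category if dbd_or_odp == "TF" else ("none" if dbd_or_odp else "none"),
                sf_subfamily=sf_sub,
                family=plan["family"],
                accessions=tuple(plan["accs"]),
            )
        )

    chunks.append(spacer(int(rng.integers(150, 400))))
    sequence = "".join(chunks)

    # sub-threshold decoys on annotated DBD proteins
    decoy_keys: list[tuple[str, str]] = []
    annotated_dbd = [g for g in genes if g.role == "annotated" and g.dbd_or_odp]
    for g in annotated_dbd:
        if rng.random() < 0.5:
            d = _decoy_hit(rng, g.protein_id, g.aa_length)
            proteome_hits.append(d)
            decoy_keys.append((d.protein_id, d.profile_accession))

    replicon = Replicon(id=rid, sequence=sequence, topology="linear", features=features)
    return PlantedGenome(
        replicon=replicon,
        genes=genes,
        proteome_hits=proteome_hits,
        orfeome_hits=orfeome_hits,
        decoy_keys=decoy_keys,
        cogs=cogs,
        seed=seed,
    )


def write_hit_tsv(hits: Iterable[RawHit], path: str | Path) -> None:
    """Serialise hits as BLAST ``-outfmt "6 std qlen slen"`` (tab-separated)."""
    with open(path, "w") as fh:
        for h in hits:
            qlen = h.query_end + 25  # plausible protein length beyond the hit
            row = (
                h.protein_id,
                h.profile_accession,
                "35.0",
                str(h.query_end - h.query_start + 1),
                "0",
                "0",
                str(h.query_start),
                str(h.query_end),
                "1",
                str(h.profile_aligned_length),
                f"{h.evalue:g}",
                f"{h.bitscore:g}",
                str(qlen),
                str(h.profile_total_length),
            )
            fh.write("\t".join(row) + "\n")
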