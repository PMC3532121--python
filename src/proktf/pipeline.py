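"""End-to-end run: ORFeome -> domain scan -> classify -> context -> report.

A run is described by a small config (YAML file or dict) naming the genome,
the domain-hit tables for the proteome and (optionally) the ORFeome, the
role registry and the output directory.  Every run writes deterministic
TSV/FASTA outputs plus a machine-readable manifest recording inputs (with
checksums), parameter values and headline counts, so a run can be audited
and reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from ._util import ProktfError, revcomp
from .classify import TFRecord, classify_all
from .context import DEFAULT_WINDOW, context_table
from .domain_scan import (
    DEFAULT_EVALUE_CUTOFF,
    DEFAULT_MIN_COVERAGE,
    architectures_from_hits,
    parse_hits,
)
from .genome_io import (
    feature_protein,
    read_cog_table,
    read_replicons,
    write_orfeome_fasta,
    write_orfeome_table,
)
from .orfeome import (
    DEFAULT_START_CODONS,
    OrfRecord,
    Replicon,
    build_orfeome,
    find_mispredicted,
)
from .registry import DomainRoleRegistry, load_default_registry
from .report import export, summarize

__all__ = ["PipelineResult", "run_pipeline", "DEFAULT_PARAMS"]

DEFAULT_PARAMS: dict[str, Any] = {
    "min_aa_length": 60,
    "start_codons": sorted(DEFAULT_START_CODONS),
    "evalue_cutoff": DEFAULT_EVALUE_CUTOFF,
    "min_coverage": DEFAULT_MIN_COVERAGE,
    "overlap_threshold": 0.1,
    "window": DEFAULT_WINDOW,
    "keep_overlaps": False,
}


@dataclass
class PipelineResult:
    out_dir: Path
    records: list[TFRecord]
    summary: Any
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ProktfError("pipeline config must be a mapping")
    return config


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, ProktfError):
                raise ProktfError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, ProktfError) and not str(exc).startswith("stage "):
                raise ProktfError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _attach_annotated(
    records: list[TFRecord], replicons: list[Replicon]
) -> list[TFRecord]:
    by_id: dict[str, tuple[Replicon, Any]] = {}
    for rep in replicons:
        for f in rep.cds_features():
            by_id[f.locus_tag] = (rep, f)
            if f.product_id:
                by_id.setdefault(f.product_id, (rep, f))
    out = []
    for r in records:
        hit = by_id.get(r.protein_id)
        if hit is None:
            out.append(r)
            continue
        rep, f = hit
        nt = rep.sequence[f.start - 1 : f.end]
        if f.strand == "-":
            nt = revcomp(nt)
        out.append(
            dc_replace(
                r,
                locus_tag=f.locus_tag,
                nt_sequence=nt,
                aa_sequence=feature_protein(rep, f),
            )
        )
    return out


def _orf_nt(rep: Replicon, orf: OrfRecord) -> str:
    if orf.wraps_origin:
        nt = rep.sequence[orf.start - 1 :] + rep.sequence[: orf.end]
    else:
        nt = rep.sequence[orf.start - 1 : orf.end]
    return nt if orf.strand == "+" else revcomp(nt)


def run_pipeline(config: dict | str | Path) -> PipelineResult:
    """Execute the full analysis described by ``config``; see module docs.

    Required config keys: ``genome``, ``proteome_hits`` (``path`` +
    ``dialect``), ``out_dir``.  Optional: ``orfeome_hits`` (enables the
    mispredicted-gene stage), ``registry`` (defaults to the shipped rules),
    ``cogs``, ``params`` overriding :data:`DEFAULT_PARAMS`.
    """
    cfg = _load_config(config)
    with _stage("validate-config"):
        for key in ("genome", "proteome_hits", "out_dir"):
            if key not in cfg:
                raise ProktfError(f"config missing required key {key!r}")
        input_paths: dict[str, Path] = {"genome": Path(cfg["genome"])}
        input_paths["proteome_hits"] = Path(cfg["proteome_hits"]["path"])
        if cfg.get("orfeome_hits"):
            input_paths["orfeome_hits"] = Path(cfg["orfeome_hits"]["path"])
        if cfg.get("registry"):
            input_paths["registry"] = Path(cfg["registry"])
        if cfg.get("cogs"):
            input_paths["cogs"] = Path(cfg["cogs"])
        for name, p in input_paths.items():
            if not p.exists():
                raise ProktfError(f"input {name!r} not found: {p}")
        params = dict(DEFAULT_PARAMS)
        params.update(cfg.get("params") or {})
        registry = (
            DomainRoleRegistry.load(cfg["registry"])
            if cfg.get("registry")
            else load_default_registry()
        )

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load-genome"):
        replicons = read_replicons(cfg["genome"])
        all_features = [f for rep in replicons for f in rep.features]
        proteome_size = sum(len(rep.cds_features()) for rep in replicons)

    with _stage("proteome-scan"):
        parse_errors: list[str] = []
        raw = parse_hits(
            cfg["proteome_hits"]["path"],
            cfg["proteome_hits"].get("dialect", "rpsblast_tab"),
            errors=parse_errors,
        )
        archs = architectures_from_hits(
            raw,
            registry,
            params["evalue_cutoff"],
            params["min_coverage"],
            keep_overlaps=params["keep_overlaps"],
        )
        records = classify_all(archs, registry, provenance="annotated")
        records = _attach_annotated(records, replicons)

    orfeome_records: list[TFRecord] = []
    orfeome_all: list[OrfRecord] = []
    if cfg.get("orfeome_hits"):
        with _stage("orfeome"):
            orf_by_id: dict[str, tuple[Replicon, OrfRecord]] = {}
            for rep in replicons:
                for orf in build_orfeome(
                    rep, params["min_aa_length"], params["start_codons"]
                ):
                    orfeome_all.append(orf)
                    orf_by_id[orf.orf_id] = (rep, orf)
            raw_orf = parse_hits(
                cfg["orfeome_hits"]["path"],
                cfg["orfeome_hits"].get("dialect", "rpsblast_tab"),
                errors=parse_errors,
            )
            raw_orf = [h for h in raw_orf if h.protein_id in orf_by_id]
            orf_archs = architectures_from_hits(
                raw_orf,
                registry,
                params["evalue_cutoff"],
                params["min_coverage"],
                keep_overlaps=params["keep_overlaps"],
            )
            candidates = classify_all(orf_archs, registry, provenance="orfeome")
            cand_orfs = [orf_by_id[r.protein_id][1] for r in candidates]
            kept = {
                o.orf_id
                for rep in replicons
                for o in find_mispredicted(
                    [c for c in cand_orfs if c.replicon_id == rep.id],
                    rep.features,
                    params["overlap_threshold"],
                    replicon_length=len(rep),
                )
            }
            for r in candidates:
                if r.protein_id not in kept:
                    continue
                rep, orf = orf_by_id[r.protein_id]
                orfeome_records.append(
                    dc_replace(
                        r,
                        mispredicted=True,
                        aa_sequence=orf.translation,
                        nt_sequence=_orf_nt(rep, orf),
                    )
                )

    all_records = records + orfeome_records

    with _stage("context"):
        cogs = read_cog_table(cfg["cogs"]) if cfg.get("cogs") else None
        ctx_frames = [
            context_table(records, rep, cogs=cogs, window=params["window"])
            for rep in replicons
        ]
        ctx = pd.concat(ctx_frames, ignore_index=True) if ctx_frames else pd.DataFrame()

    with _stage("summarize"):
        summary = summarize(
            all_records, proteome_size, replicon_ids=[r.id for r in replicons]
        )
        summary.check()
        proteome_tf = sum(
            1 for r in records if r.dbd_or_odp == "TF" and not r.mispredicted
        )
        mis_tf = sum(1 for r in orfeome_records if r.dbd_or_odp == "TF")
        gain_pct = round(100.0 * mis_tf / proteome_tf, 2) if proteome_tf else None

    with _stage("export"):
        export(all_records, "tsv", out_dir / "tf_table.tsv")
        export(orfeome_records, "tsv", out_dir / "mispredicted.tsv")
        if all(r.aa_sequence for r in all_records):
            export(all_records, "fasta_aa", out_dir / "tf_proteins.faa")
        if all(r.nt_sequence for r in all_records):
            export(all_records, "fasta_nt", out_dir / "tf_genes.fna")
        ctx.to_csv(out_dir / "context.tsv", sep="\t", index=False)
        if orfeome_all:
            write_orfeome_table(orfeome_all, out_dir / "orfeome.tsv")
            write_orfeome_fasta(orfeome_all, out_dir / "orfeome.faa")
        _write_summary_tsv(summary, gain_pct, out_dir / "summary.tsv")
        manifest = {
            "proktf_version": __version__,
            "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in input_paths.items()},
            "params": params,
            "counts": {
                "proteome_size": proteome_size,
                "total_dbd": summary.total_dbd,
                "tf": summary.tf_count,
                "odp": summary.odp_count,
                "categories": summary.category_counts,
                "sf_subfamilies": summary.sf_subfamily_counts,
                "mispredicted": summary.mispredicted_count,
                "mispredicted_tf_gain_pct": gain_pct,
                "pct_dbd_of_proteome": summary.pct_dbd_of_proteome,
                "hit_rows_rejected": len(parse_errors),
            },
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(out_dir, all_records, summary, manifest)


def _write_summary_tsv(summary, gain_pct, path: Path) -> None:
    rows = [
        ("replicons", ",".join(summary.replicon_ids)),
        ("proteome_size", summary.proteome_size),
        ("total_dbd_proteins", summary.total_dbd),
        ("tf", summary.tf_count),
        ("odp", summary.odp_count),
    ]
    rows += [(f"category_{k}", v) for k, v in summary.category_counts.items()]
    rows += [(f"sf_{k}", v) for k, v in summary.sf_subfamily_counts.items()]
    rows += [(f"family_{k}", v) for k, v in summary.family_counts.items()]
    rows += [
        ("mispredicted", summary.mispredicted_count),
        (
            "pct_dbd_of_proteome",
            "" if summary.pct_dbd_of_proteome is None else summary.pct_dbd_of_proteome,
        ),
        ("mispredicted_tf_gain_pct", "" if gain_pct is None else gain_pct),
    ]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, sep="\t", index=False)
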