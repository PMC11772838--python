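"""End-to-end orchestration of the splicing-accuracy stages.

Stages run in dependency order (io -> qc/classify -> msr -> scoring ->
geometry -> modelling -> comparison), never mutate their inputs, and write
only tab-separated intermediates. A manifest of output checksums supports
byte-level reproducibility checks for the deterministic stages; a rerun with
the same config and inputs reproduces their checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import annotation as ann_io
from . import geometry as geo
from . import metrics
from . import modeling
from . import scoring
from .classify import classify_junctions
from .compare import adjust_pvalues, pooled_msr_comparison, read_sample_metadata
from .junctions import merge_junctions, read_junctions

logger = logging.getLogger(__name__)

ALL_STAGES = ("classify", "msr", "score", "geometry", "model", "compare")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    gtf: str = ""
    fasta: str = ""
    junctions_dir: str = ""
    metadata: str = ""
    outdir: str = "out"
    blacklist: str = ""
    minor_introns: str = ""
    conservation: str = ""
    constraint: str = ""
    mane: str = ""
    stages: tuple[str, ...] = ALL_STAGES
    min_length: int = 25
    max_distance: int = 100
    rin_tolerance: float = 0.05
    expr_match: float = 0.005
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a plain ``key = value`` config file."""
        kwargs = {}
        for ln, line in enumerate(open(path), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PipelineError(f"{path}:{ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "stages":
                kwargs[key] = tuple(s.strip() for s in value.split(","))
            elif key in ("min_length", "max_distance", "seed"):
                kwargs[key] = int(value)
            elif key in ("rin_tolerance", "expr_match"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if key == "stages":
                    value = ",".join(value)
                fh.write(f"{key} = {value}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageWriter:
    """Writes stage outputs atomically; failures leave quarantined partials."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.pending: list[tuple[Path, Path]] = []

    def target(self, name: str) -> Path:
        tmp = self.outdir / (name + ".tmp")
        self.pending.append((tmp, self.outdir / name))
        return tmp

    def commit(self) -> list[Path]:
        final = []
        for tmp, dest in self.pending:
            tmp.replace(dest)
            final.append(dest)
        self.pending = []
        return final

    def quarantine(self) -> None:
        for tmp, dest in self.pending:
            if tmp.exists():
                tmp.replace(dest.with_suffix(dest.suffix + ".quarantine"))
        self.pending = []


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the enabled stages and return the output manifest (path -> sha256)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "resolved_config.txt")
    manifest: dict[str, str] = {}
    outputs: list[Path] = [outdir / "resolved_config.txt"]
    state: dict = {}

    stage_fns = {
        "classify": _stage_classify,
        "msr": _stage_msr,
        "score": _stage_score,
        "geometry": _stage_geometry,
        "model": _stage_model,
        "compare": _stage_compare,
    }
    for name in ALL_STAGES:
        if name not in config.stages:
            continue
        writer = _StageWriter(outdir)
        t0 = time.monotonic()
        try:
            stage_fns[name](config, state, writer)
            outputs.extend(writer.commit())
        except Exception as exc:
            writer.quarantine()
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: %.2fs", name, time.monotonic() - t0)

    for path in outputs:
        manifest[path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    if "annotation" in state:
        return
    mane_ids = None
    if config.mane:
        mane_ids = {l.strip() for l in open(config.mane) if l.strip()}
    state["annotation"] = ann_io.load_annotation(config.gtf, mane_ids=mane_ids)
    state["blacklist"] = (
        ann_io.read_region_mask(config.blacklist) if config.blacklist else None
    )
    state["minor"] = (
        ann_io.read_region_mask(config.minor_introns) if config.minor_introns else None
    )
    sj_files = sorted(Path(config.junctions_dir).glob("*.SJ.out.tab"))
    if not sj_files:
        raise PipelineError(f"no *.SJ.out.tab files in {config.junctions_dir}")
    per_sample = [
        read_junctions(p, dialect="star_sj", sample_id=p.name.removesuffix(".SJ.out.tab"))
        for p in sj_files
    ]
    state["samples"] = [p.name.removesuffix(".SJ.out.tab") for p in sj_files]
    state["junctions"] = merge_junctions(per_sample)
    state["metadata"] = (
        read_sample_metadata(config.metadata) if config.metadata else []
    )


def _stage_classify(config, state, writer) -> None:
    _load_inputs(config, state)
    classified = classify_junctions(
        state["junctions"],
        state["annotation"],
        blacklist=state["blacklist"],
        minor_introns=state["minor"],
        min_length=config.min_length,
    )
    state["classified"] = classified
    rows = []
    for cj in classified:
        j = cj.junction
        rows.append(
            {
                "chrom": j.chrom, "start": j.start, "end": j.end, "strand": j.strand,
                "category": cj.category,
                "assigned_intron": cj.assigned_intron_id or ".",
                "qc_flags": ",".join(sorted(cj.qc_flags)) or ".",
                "total_count": j.total_count(),
            }
        )
    pd.DataFrame(rows).to_csv(writer.target("classified.tsv"), sep="\t", index=False)


def _stage_msr(config, state, writer) -> None:
    if "classified" not in state:
        raise PipelineError("msr stage requires the classify stage")
    groups: dict[str, list[str]] = {}
    for meta in state["metadata"]:
        groups.setdefault(meta.group, []).append(meta.sample_id)
    if not groups:
        groups = {"all": state["samples"]}
    frames = []
    for label, samples in sorted(groups.items()):
        recs = metrics.msr_table(state["classified"], samples, group_label=label)
        frames.append(metrics.msr_frame(recs))
    state["msr"] = pd.concat(frames)
    state["matrices"] = metrics.msr_matrix_by_sample(state["classified"], state["samples"])
    state["msr"].to_csv(writer.target("msr.tsv"), sep="\t")
    summary = metrics.category_percentages(state["classified"], state["samples"])
    pd.DataFrame(
        [{**{"pj_" + k: v for k, v in summary.pct_unique.items()},
          **{"pr_" + k: v for k, v in summary.pct_reads.items()}}]
    ).to_csv(writer.target("category_percentages.tsv"), sep="\t", index=False)


def _stage_score(config, state, writer) -> None:
    if "classified" not in state:
        raise PipelineError("score stage requires the classify stage")
    genome = Fasta(config.fasta)
    model = scoring.train_from_annotation(state["annotation"], genome)
    state["site_model"] = model
    deltas = scoring.delta_scores(model, state["classified"], state["annotation"], genome)
    pd.DataFrame(
        [
            {
                "intron_id": d.intron_id,
                "junction": "{}:{}-{}({})".format(*d.novel_junction_key),
                "site_kind": d.site_kind,
                "annotated_score": d.annotated_score,
                "novel_score": d.novel_score,
                "delta": d.delta,
            }
            for d in deltas
        ]
    ).to_csv(writer.target("delta_scores.tsv"), sep="\t", index=False)


def _stage_geometry(config, state, writer) -> None:
    if "classified" not in state:
        raise PipelineError("geometry stage requires the classify stage")
    distances = geo.site_distances(state["classified"], state["annotation"])
    pd.DataFrame(
        [
            {
                "junction": "{}:{}-{}({})".format(*d.novel_junction_key),
                "intron_id": d.intron_id,
                "site_kind": d.site_kind,
                "raw_distance": d.raw_distance,
                "distance": d.distance,
                "mod3": d.mod3,
            }
            for d in distances
        ]
    ).to_csv(writer.target("distances.tsv"), sep="\t", index=False)
    profile = geo.mod3_profile(
        distances, state["annotation"], max_abs_distance=config.max_distance
    )
    density = geo.positional_density(distances)
    pd.DataFrame(
        [
            {
                "mod3_0": profile.proportions[0],
                "mod3_1": profile.proportions[1],
                "mod3_2": profile.proportions[2],
                "n_mod3": profile.n,
                "acceptor_asymmetry": density.acceptor_asymmetry,
            }
        ]
    ).to_csv(writer.target("geometry_summary.tsv"), sep="\t", index=False)


def _stage_model(config, state, writer) -> None:
    if "msr" not in state or "site_model" not in state:
        raise PipelineError("model stage requires the msr and score stages")
    genome = Fasta(config.fasta)
    conservation = ann_io.read_score_track(config.conservation)
    constraint = ann_io.read_score_track(config.constraint)
    all_samples = state["samples"]
    recs = metrics.msr_table(state["classified"], all_samples, group_label="all")
    for kind in ("donor", "acceptor"):
        features = modeling.build_feature_table(
            recs, state["annotation"], state["site_model"], genome,
            conservation, constraint, msr_kind=kind,
        )
        fit = modeling.fit_zip(features)
        pd.DataFrame(
            {
                "beta": fit.count_params,
                "robust_se": fit.count_bse,
                "exp_beta": fit.exp_params,
                "p": fit.pvalues,
                "q": fit.qvalues,
            }
        ).to_csv(writer.target(f"zip_{kind}.tsv"), sep="\t")


def _stage_compare(config, state, writer) -> None:
    if "matrices" not in state:
        raise PipelineError("compare stage requires the msr stage")
    groups: dict[str, list[str]] = {}
    for meta in state["metadata"]:
        groups.setdefault(meta.group, []).append(meta.sample_id)
    if len(groups) < 2:
        raise PipelineError("compare stage requires >= 2 sample groups in metadata")
    labels = sorted(groups)
    a, b = labels[0], labels[1]
    mats = state["matrices"]
    results = []
    for kind, mat in (("donor", mats["novel_donor"]), ("acceptor", mats["novel_acceptor"])):
        res = pooled_msr_comparison(
            mat, mats["annotated"], groups[a], groups[b], sided="one_greater"
        )
        results.append((kind, res))
    adjusted = adjust_pvalues([r.p for _, r in results], method="BH")
    pd.DataFrame(
        [
            {
                "site_kind": kind,
                "group_a": a,
                "group_b": b,
                "test": r.test,
                "sidedness": r.sidedness,
                "statistic": r.statistic,
                "p": r.p,
                "q": q,
                "effect_size": r.effect_size,
                "n_introns": r.n,
            }
            for (kind, r), q in zip(results, adjusted)
        ]
    ).to_csv(writer.target("comparisons.tsv"), sep="\t", index=False)
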