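"""End-to-end orchestration: filter → signatures → embedding → selection → assessment.

A run is described by a :class:`RunConfig`; every run writes a manifest
(JSON) that records all materialized parameters, the seed, input
checksums and stage counts, and which suffices to reproduce the run
bit-for-bit (serial execution).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .assessment import read_marker_table
from .embedding import TsneParams, run_tsne
from .io_formats import (
    read_annotations,
    read_fasta,
    write_bin_fasta,
    write_embedding,
)
from .selection import compute_visual_attributes, load_polygons, plot_embedding, select_cluster
from .signatures import SignatureOptions, compute_signature_matrix

__all__ = ["RunConfig", "run_pipeline", "run_from_manifest"]

logger = logging.getLogger("sigbin")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, with all defaults materialized."""

    fasta: str
    outdir: str
    annotations: str | None = None
    polygons: str | None = None
    markers: str | None = None
    min_length: int = 1000
    signature_options: SignatureOptions = field(default_factory=SignatureOptions)
    tsne_params: TsneParams = field(default_factory=TsneParams)
    make_plot: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["signature_options"] = SignatureOptions(**d.get("signature_options", {}))
        d["tsne_params"] = TsneParams(**d.get("tsne_params", {}))
        return cls(**d)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest (also written).

    Optional stages (annotation, polygon selection, bin assessment) run
    only when their inputs are configured. Errors carry a stage label.
    """
    import numpy

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {"sigbin": __version__, "numpy": numpy.__version__},
        "config": config.to_dict(),
        "inputs": {},
        "counts": {},
        "artifacts": [],
    }

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("filter")
        manifest["inputs"]["fasta_sha256"] = _sha256(config.fasta)
        fasta = read_fasta(config.fasta, min_length=config.min_length)
        manifest["counts"]["input_records"] = fasta.n_input
        manifest["counts"]["filtered_records"] = len(fasta.records)
        logger.info(
            "read %d records, kept %d of length >= %d nt",
            fasta.n_input, len(fasta.records), config.min_length,
        )
    except Exception as exc:
        raise RuntimeError(f"[filter] {exc}") from exc

    annotations = None
    if config.annotations:
        try:
            _stage("annotations")
            manifest["inputs"]["annotations_sha256"] = _sha256(config.annotations)
            annotations = read_annotations(config.annotations, fasta)
        except Exception as exc:
            raise RuntimeError(f"[annotations] {exc}") from exc

    try:
        _stage("signatures")
        sig = compute_signature_matrix(fasta.records, config.signature_options)
    except Exception as exc:
        raise RuntimeError(f"[signatures] {exc}") from exc

    try:
        _stage("embedding")
        result = run_tsne(sig, config.tsne_params)
        manifest["counts"]["embedded_points"] = len(result.coords)
        emb_path = outdir / "embedding.csv"
        write_embedding(emb_path, sig.ids, result.coords)
        manifest["artifacts"].append(str(emb_path))
        trace_path = outdir / "kl_trace.csv"
        with open(trace_path, "w") as fh:
            fh.write("iteration,kl\n")
            for it, kl in result.kl_trace:
                fh.write(f"{it},{kl!r}\n")
        manifest["artifacts"].append(str(trace_path))
    except Exception as exc:
        raise RuntimeError(f"[embedding] {exc}") from exc

    if config.make_plot:
        try:
            _stage("plot")
            attrs = None
            if annotations is not None:
                attrs = compute_visual_attributes(
                    annotations, [r.length for r in fasta.records]
                )
            polys = load_polygons(config.polygons) if config.polygons else None
            plot_path = outdir / "embedding.png"
            plot_embedding(result, plot_path, attributes=attrs, polygons=polys)
            manifest["artifacts"].append(str(plot_path))
        except Exception as exc:
            raise RuntimeError(f"[plot] {exc}") from exc

    selections: dict[str, list[str]] = {}
    if config.polygons:
        try:
            _stage("selection")
            manifest["inputs"]["polygons_sha256"] = _sha256(config.polygons)
            polygons = load_polygons(config.polygons)
            manifest["counts"]["selected_points"] = {}
            for name, poly in polygons.items():
                ids = select_cluster(result, poly)
                selections[name] = ids
                logger.info("polygon %s selected %d points", name, len(ids))
                manifest["counts"]["selected_points"][name] = len(ids)
                bin_path = outdir / f"{name}.fasta"
                write_bin_fasta(fasta.records, ids, bin_path)
                manifest["artifacts"].append(str(bin_path))
        except Exception as exc:
            raise RuntimeError(f"[selection] {exc}") from exc

    if config.markers and selections:
        try:
            _stage("assessment")
            manifest["inputs"]["markers_sha256"] = _sha256(config.markers)
            markers = read_marker_table(config.markers)
            from .assessment import assess_bin

            report_path = outdir / "bin_stats.csv"
            with open(report_path, "w") as fh:
                fh.write("bin,n_contigs,mbp,single_copy,multiple_copies,completeness\n")
                for name, ids in selections.items():
                    stats = assess_bin(ids, fasta.records, markers, name=name)
                    fh.write(
                        f"{stats.name},{stats.n_contigs},{stats.total_mbp:.2f},"
                        f"{stats.single_copy},{stats.multiple_copies},"
                        f"{stats.completeness:.4f}\n"
                    )
            manifest["artifacts"].append(str(report_path))
        except Exception as exc:
            raise RuntimeError(f"[assessment] {exc}") from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def run_from_manifest(manifest_path: str | Path, outdir: str | None = None) -> dict:
    """Re-execute a run from its manifest; reproduces all artifacts exactly."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    if outdir is not None:
        config.outdir = outdir
    return run_pipeline(config)
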