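"""End-to-end pipeline: simulate (or ingest) -> demux -> QC -> fit -> compare.

One master seed drives every stage through deterministically spawned
per-stage child seeds (numpy SeedSequence), so the manifest seed plus the
config fully determine all outputs.  Each stage writes its declared
tables; a JSON manifest records parameters, seeds and SHA-256 hashes of
every per-stage input and output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demux_counts, qc_filters, spike_mixture, summary_compare
from .synthetic_data import (DEFAULT_TEMPLATE, SequencingSpec, SubsetTruth,
                             barcode_table, build_plates, emit_fastq)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("mtspike")

_STAGES = ("simulate", "demux", "qc", "fit", "compare")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full run; see `example_config()` for a template."""

    subsets: list                      # list of SubsetTruth
    sequencing: SequencingSpec = dataclasses.field(
        default_factory=SequencingSpec)
    qc: qc_filters.QCConfig = dataclasses.field(
        default_factory=qc_filters.QCConfig)
    model: spike_mixture.MixtureModelSpec = dataclasses.field(
        default_factory=spike_mixture.MixtureModelSpec)
    comparison_order: list = dataclasses.field(
        default_factory=lambda: ["naive", "CM", "EM", "TEMRA"])
    comparison_groups: list | None = None
    use_fastq: bool = False
    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 4
    n_chains: int = 4
    seed: int = 0


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; keys mirror the stage dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    subsets = [SubsetTruth(**{**s, "slab": tuple(s.get("slab", ("uniform",)))})
               for s in raw.pop("subsets")]
    kwargs = {}
    if "sequencing" in raw:
        kwargs["sequencing"] = SequencingSpec(**raw.pop("sequencing"))
    if "qc" in raw:
        kwargs["qc"] = qc_filters.QCConfig(**raw.pop("qc"))
    if "model" in raw:
        kwargs["model"] = spike_mixture.MixtureModelSpec(**raw.pop("model"))
    return PipelineConfig(subsets=subsets, **kwargs, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_rngs(master_seed: int) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return dict(zip(_STAGES, children))


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir,
                 counts_path=None) -> dict:
    """Execute all stages into ``out_dir`` and return the manifest dict.

    With ``counts_path`` the simulate/demux stages are skipped and the
    per-well counts table (TSV with plate_id, well_id, subject_id,
    cell_type, is_negative_control, ref_count, alt_count, depth) is
    ingested instead.  Partial outputs are retained when a stage fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(config.seed)
    # the manifest is fully determined by seed + config (no wall-clock
    # fields), so byte-identical reruns are checkable by file hash
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "parameters": {
            "n_iter": config.n_iter, "burn_in": config.burn_in,
            "thin": config.thin, "n_chains": config.n_chains,
            "use_fastq": config.use_fastq,
            "sequencing": dataclasses.asdict(config.sequencing),
            "qc": dataclasses.asdict(config.qc),
            "model": dataclasses.asdict(config.model),
            "subsets": [dataclasses.asdict(s) for s in config.subsets],
        },
    }

    def record(stage, outputs, t0):
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        log.info("stage=%s done in %.2fs", stage, time.time() - t0)

    # -- simulate / ingest ---------------------------------------------------
    t0 = time.time()
    if counts_path is None:
        rng = np.random.default_rng(rngs["simulate"])
        plates, truth = build_plates(config.subsets, config.sequencing, rng)
        truth_path = out / "truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        bc = barcode_table(plates)
        bc_path = out / "barcodes.tsv"
        bc.to_csv(bc_path, sep="\t", index=False)
        outputs = [truth_path, bc_path]
        if config.use_fastq:
            fq_path = out / "reads.fastq"
            emit_fastq(plates, truth, DEFAULT_TEMPLATE, config.sequencing,
                       rng, fq_path)
            outputs.append(fq_path)
        record("simulate", outputs, t0)

        # -- demux (FASTQ path) or direct counts -----------------------------
        t0 = time.time()
        meta_cols = ["plate_id", "well_id", "subject_id", "cell_type",
                     "is_negative_control"]
        meta = truth[meta_cols]
        if config.use_fastq:
            counted = demux_counts.demux_and_count(
                fq_path, bc, DEFAULT_TEMPLATE.target_offset,
                template=DEFAULT_TEMPLATE)
            counts = meta.merge(counted, on=["plate_id", "well_id"],
                                how="left")
            for c in ("ref_count", "alt_count", "depth",
                      "n_discarded_low_quality"):
                counts[c] = counts[c].fillna(0).astype(int)
        else:
            counts = truth[meta_cols + ["ref_count", "alt_count",
                                        "depth"]].copy()
            with np.errstate(invalid="ignore"):
                counts["vaf"] = np.where(
                    counts["depth"] > 0,
                    counts["alt_count"] / counts["depth"].replace(0, 1),
                    np.nan)
        counts_file = out / "counts.tsv"
        counts.to_csv(counts_file, sep="\t", index=False)
        record("demux", [counts_file], t0)
    else:
        counts = pd.read_csv(counts_path, sep="\t")
        required = {"plate_id", "well_id", "subject_id", "cell_type",
                    "is_negative_control", "ref_count", "alt_count", "depth"}
        if not required <= set(counts.columns):
            raise StageError("demux",
                             f"counts table needs columns {sorted(required)}")
        counts["vaf"] = np.where(counts["depth"] > 0,
                                 counts["alt_count"]
                                 / counts["depth"].replace(0, 1), np.nan)
        counts_file = out / "counts.tsv"
        counts.to_csv(counts_file, sep="\t", index=False)
        record("ingest", [counts_file], t0)

    # -- QC ------------------------------------------------------------------
    t0 = time.time()
    try:
        retained, report = qc_filters.apply_qc(counts, config.qc)
    except ValueError as e:
        raise StageError("qc", str(e)) from e
    retained_path = out / "retained_cells.tsv"
    retained.to_csv(retained_path, sep="\t", index=False)
    qc_path = out / "qc_report.json"
    qc_path.write_text(json.dumps(report.to_dict(), indent=2))
    record("qc", [retained_path, qc_path], t0)

    # -- fit per (subject, cell type) ----------------------------------------
    t0 = time.time()
    fit_seed_root = rngs["fit"]
    fits = {}
    summaries = []
    groups = sorted(retained.groupby(["subject_id", "cell_type"]).groups)
    fit_seeds = fit_seed_root.spawn(len(groups))
    draws_dir = out / "draws"
    draws_dir.mkdir(exist_ok=True)
    draw_files = []
    for (subject, ct), child in zip(groups, fit_seeds):
        sub = retained[(retained["subject_id"] == subject)
                       & (retained["cell_type"] == ct)]
        vaf = sub["alt_count"].to_numpy() / sub["depth"].to_numpy()
        y, n_nudged = spike_mixture.nudge_boundary(
            vaf, sub["depth"].to_numpy())
        draws = spike_mixture.fit_mcmc(
            y, config.model, n_iter=config.n_iter, burn_in=config.burn_in,
            thin=config.thin, n_chains=config.n_chains,
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        fits[(subject, ct)] = draws
        df = pd.DataFrame({
            "chain": np.repeat(np.arange(draws.pi.shape[0]),
                               draws.pi.shape[1]),
            "s": draws.s.reshape(-1), "pi": draws.pi.reshape(-1),
            "mu": draws.mu.reshape(-1), "sigma": draws.sigma.reshape(-1),
        })
        f = draws_dir / f"{subject}_{ct}.tsv"
        df.to_csv(f, sep="\t", index=False)
        draw_files.append(f)
        summaries.append({
            "subject": subject, "cell_type": ct, "n_cells": int(len(sub)),
            "n_boundary_nudged": n_nudged,
            "p_no_spike": draws.p_no_spike, "mean_pi": draws.mean_pi,
            "rhat_pi": draws.meta["rhat_pi"],
        })
    fit_path = out / "fit_summary.tsv"
    pd.DataFrame(summaries).to_csv(fit_path, sep="\t", index=False)
    record("fit", [fit_path, *draw_files], t0)

    # -- compare -------------------------------------------------------------
    t0 = time.time()
    order = [ct for ct in config.comparison_order
             if any(ct == k[1] for k in fits)]
    extra = sorted({k[1] for k in fits} - set(order))
    summary, comparisons = summary_compare.gradient_report(
        fits, order + extra, groups=config.comparison_groups)
    s_path = out / "peak_summary.tsv"
    c_path = out / "comparisons.tsv"
    summary.to_csv(s_path, sep="\t", index=False)
    comparisons.to_csv(c_path, sep="\t", index=False)
    record("compare", [s_path, c_path], t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
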