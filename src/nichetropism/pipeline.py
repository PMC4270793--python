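"""End-to-end pipeline: obtain densities, classify, summarize, test.

``run_pipeline`` chains the stages the individual modules expose — synthetic
(or loaded) per-hub densities → tropism classification and per-line
frequency/density summaries → compact-letter group comparisons → parsimony
randomization against a phylogeny — and writes a reproducible report bundle
plus a manifest of all parameters and seeds.  Fully deterministic under a
fixed configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, io
from .group_stats import assign_letters
from .image_quant import HubDensityTable, mean_density_ratio, tropism_frequency
from .phylosignal import ParsimonyRandomization, bin_frequency, load_tree, trace_report
from .synthetic_data import simulate_density_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("densities")
def _obtain_table(config: io.PipelineConfig) -> HubDensityTable:
    if config.simulate:
        records = []
        for i, spec in enumerate(config.simulate):
            spec = dict(spec)
            line_id = spec.pop("line_id", f"line{i + 1}")
            # derived per-line seed keeps lines independent yet reproducible
            seed = spec.pop("seed", (config.seed * 1000 + i) % (2**31 - 1))
            table = simulate_density_table(
                line_id=line_id, seed=seed, threshold=config.threshold, **spec
            )
            records.extend(table.records)
        return HubDensityTable(records)
    if config.density_table:
        return io.read_density_table(
            config.density_table,
            threshold=config.threshold,
            aggregation=config.aggregation,
        )
    raise ValueError("config must provide either 'simulate' cohorts or a 'density_table'")


@_stage("frequency")
def _frequency_frame(table: HubDensityTable, config: io.PipelineConfig) -> pd.DataFrame:
    rows = []
    for line_id in table.line_ids:
        est = tropism_frequency(table, line_id, ci_method=config.ci_method)
        mean, sem = mean_density_ratio(table, line_id)
        rows.append(
            {
                "line_id": line_id,
                "k": est.k,
                "n": est.n,
                "frequency_percent": est.frequency,
                "ci_low": est.ci95[0],
                "ci_high": est.ci95[1],
                "mean_ratio": mean,
                "sem_ratio": sem,
                "state": bin_frequency(est.frequency),
            }
        )
    return pd.DataFrame(rows)


@_stage("lettering")
def _letter_frames(
    table: HubDensityTable, freq: pd.DataFrame, config: io.PipelineConfig
) -> dict:
    out: dict = {}
    if len(freq) >= 2:
        counts = {row.line_id: (int(row.k), int(row.n)) for row in freq.itertuples()}
        freq_letters = assign_letters(counts, alpha=config.alpha, test="proportion")
        samples = {
            line: [r.ratio for r in table.for_line(line) if r.ratio_defined]
            for line in table.line_ids
        }
        dens_letters = assign_letters(samples, alpha=config.alpha, test="t")
        out["frequency_letters"] = pd.DataFrame(
            sorted(freq_letters.letters.items()), columns=["line_id", "letters"]
        )
        out["frequency_pairwise"] = freq_letters.pairwise
        out["density_letters"] = pd.DataFrame(
            sorted(dens_letters.letters.items()), columns=["line_id", "letters"]
        )
        out["density_pairwise"] = dens_letters.pairwise
    return out


@_stage("phylosignal")
def _phylosignal(config: io.PipelineConfig, freq: pd.DataFrame) -> dict | None:
    if config.use_bundled_phylogeny:
        tree = datasets.load_wolbachia_tree()
        states = datasets.wolbachia_character()
    elif config.tree:
        tree = load_tree(config.tree)
        if config.traits:
            traits = io.read_traits(config.traits)
            if "state" in traits.columns:
                states = dict(zip(traits["leaf_label"], traits["state"]))
            else:
                states = {
                    row.leaf_label: bin_frequency(row.frequency_percent)
                    for row in traits.itertuples()
                }
        else:
            states = dict(
                zip(freq["line_id"], freq["state"])
            )
    else:
        return None
    model = ParsimonyRandomization(tree, states, null_model=config.null_model)
    result = model.fit(n_random=config.n_random, seed=config.seed)
    report = trace_report(tree, states, result)
    logger.info(
        "phylosignal: observed %d steps, p = %.4g over %d random characters",
        result.observed_length,
        result.p_value,
        result.n_random,
    )
    return report


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns the in-memory bundle; on disk, ``output_dir`` receives the long
    and per-hub density CSVs, the per-line summary CSV, the JSON report and a
    ``manifest.json`` sufficient to reproduce the run.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    table = _obtain_table(config)
    n_undefined = sum(1 for r in table if not r.ratio_defined)
    logger.info(
        "densities: %d hubs in %d lines (%d excluded for undefined ratios)",
        len(table),
        len(table.line_ids),
        n_undefined,
    )
    freq = _frequency_frame(table, config)
    letters = _letter_frames(table, freq, config)
    signal = _phylosignal(config, freq)

    io.write_density_table(table, outdir / "densities_long.csv")
    io.write_hub_summary(table, outdir / "densities_hubs.csv")
    freq.to_csv(outdir / "line_summary.csv", index=False)

    bundle: dict = {
        "n_hubs": len(table),
        "n_lines": len(table.line_ids),
        "n_excluded_undefined_ratio": n_undefined,
        "line_summary": freq,
    }
    bundle.update(letters)
    if signal is not None:
        bundle.update(
            {
                "phylosignal_observed_length": signal["observed_length"],
                "phylosignal_p_value": signal["p_value"],
                "phylosignal_null_histogram": signal["null_histogram"],
            }
        )
    io.write_report(bundle, outdir / "report.json", format="json")
    io.write_manifest(
        config,
        outdir / "manifest.json",
        extra={"n_hubs": len(table), "n_excluded": n_undefined},
    )
    return bundle
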