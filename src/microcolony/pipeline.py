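"""End-to-end analysis pipeline: classification, the four mechanism tests,
and growth rate, on one lineage table (read from disk or simulated).

Stages run in dependency order; every stage writes a delimited artifact so
each can be re-run standalone, and the final plain-text report is
regenerable from the stage outputs.  One global seed is split into
independent per-stage streams so partial re-runs stay reproducible.

No correction for multiple testing is applied across the four mechanism
tests; the report states this explicitly, and downstream users should treat
the four p-values as separate, uncorrected hypotheses.
"""

from __future__ import annotations

import collections
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growth, oscillation, switching, transmission
from .age import assign_pole_ages, compare_age_classes
from .lineage import (
    LineageTree,
    classify,
    fit_gmm_threshold,
    read_lineage_table,
    write_lineage_table,
)
from .simulate import SimulationConfig, simulate_colony
from .skewness import fisher_pearson_skewness, skewness_randomization_test

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration."""

    input_table: str | None = None       # lineage CSV; or simulate a regime
    simulate_regime: str | None = None
    n_generations: int = 6
    seed: int = 0
    n_shuffles: int = 500                # HMM shuffle replicates
    n_perm: int = 2000                   # localization permutations
    n_draws: int = 20000                 # skewness null draws
    run_oscillation: bool = True         # GP stage is the slow one
    outdir: str = "pipeline_out"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        casts = {
            "n_generations": int, "seed": int, "n_shuffles": int,
            "n_perm": int, "n_draws": int,
            "run_oscillation": lambda v: v.lower() in ("1", "true", "yes"),
        }
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                k, _, v = line.partition("=")
                k, v = k.strip(), v.strip()
                if k not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown config key {k!r}")
                kwargs[k] = casts.get(k, str)(v)
        return cls(**kwargs)


@dataclass
class PipelineReport:
    skewness: dict = field(default_factory=dict)
    threshold: float | None = None
    gmm_params: list = field(default_factory=list)
    hmm_edges: list = field(default_factory=list)
    oscillation: dict | None = None
    age: dict | None = None
    spatial: dict | None = None
    growth_rate: dict | None = None
    stages_failed: dict = field(default_factory=dict)
    seed: int = 0

    def to_text(self) -> str:
        lines = ["# microcolony pipeline report", f"seed = {self.seed}", ""]
        sk = self.skewness
        lines += [
            "## population diversity (final-frame ATP)",
            f"skewness g1 = {sk.get('g1'):.4f}   randomization p = {sk.get('p')}",
            "",
            "## global high/low threshold",
            f"threshold = {self.threshold:.4f} mM"
            if self.threshold is not None else "threshold: unavailable",
            "",
            "## stochastic switching (2-state HMM, shuffle null)",
        ]
        for row in self.hmm_edges:
            lines.append(
                f"{row['edge']:12s} observed={row['observed']:.4f} "
                f"null5={row['p5']:.4f} null95={row['p95']:.4f} {row['verdict']}"
            )
        if self.oscillation is not None:
            lines += ["", "## periodic oscillation (GP features, rank-sum by class)"]
            for feat, rep in self.oscillation.items():
                lines.append(
                    f"{feat}: U={rep['U']:.1f} p={rep['p']:.4g} "
                    f"median HIGH={rep['median_high']:.3g} LOW={rep['median_low']:.3g}"
                )
        if self.age is not None:
            lines += [
                "", "## cellular age (pole age, rank-sum by class)",
                f"U={self.age['U']:.1f} p={self.age['p']:.4g} "
                f"median HIGH={self.age['median_high']} LOW={self.age['median_low']}",
            ]
        if self.spatial is not None:
            sp = self.spatial
            lines += [
                "", "## intercellular transmission (spatial analysis)",
                f"localization p = {sp['localization_p']}",
                f"dER/dNB = {sp['ratio_spatial']['mean']:.3f} "
                f"[{sp['ratio_spatial']['lower']:.3f}, {sp['ratio_spatial']['upper']:.3f}] "
                f"reject H0: {sp['ratio_spatial']['reject']}",
                f"dED/dCR = {sp['ratio_lineage']['mean']:.3f} "
                f"[{sp['ratio_lineage']['lower']:.3f}, {sp['ratio_lineage']['upper']:.3f}] "
                f"reject H0: {sp['ratio_lineage']['reject']}",
            ]
        if self.growth_rate is not None:
            g = self.growth_rate
            lines += [
                "", "## growth rate (generalized Euler-Lotka)",
                f"Lambda = {g['Lambda']:.4f} /h  (Delta={g['Delta']}, "
                f"n_lineages={g['n_lineages']})",
            ]
        for stage, err in self.stages_failed.items():
            lines += ["", f"## STAGE FAILED: {stage}", str(err)]
        lines += [
            "",
            "note: the four mechanism tests are reported without multiple-",
            "testing correction (four separate uncorrected hypotheses).",
        ]
        return "\n".join(lines) + "\n"


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage on the configured input; artifacts go to outdir.

    A stage failure is recorded in the report (with the stage name) and the
    remaining independent stages still run; completed artifacts are kept.
    """
    if config.input_table is None and config.simulate_regime is None:
        raise ValueError("config needs input_table or simulate_regime")
    os.makedirs(config.outdir, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report = PipelineReport(seed=config.seed)

    if config.input_table is not None:
        tree = read_lineage_table(config.input_table)
    else:
        sim_cfg = SimulationConfig(
            regime=config.simulate_regime,
            n_generations=config.n_generations,
            seed=seeds[0],
        )
        tree = simulate_colony(sim_cfg)
        write_lineage_table(tree, os.path.join(config.outdir, "lineage_table.csv"))

    # skewness of the final-frame ATP distribution
    last = max(o.frame for c in tree.cells.values() for o in c.observations
               if not o.placeholder)
    final_atp = [
        o.atp_mM for c in tree.cells.values() for o in c.observations
        if o.frame == last and not o.placeholder and o.atp_mM is not None
    ]
    sk = skewness_randomization_test(final_atp, n_draws=config.n_draws, seed=seeds[1])
    report.skewness = {"g1": sk.g1, "p": sk.p_value, "n": sk.n}

    # global threshold + classification
    all_vals = np.concatenate([c.atp_trace() for c in tree.cells.values()])
    bc = fit_gmm_threshold(all_vals, seed=seeds[2])
    report.threshold = bc.threshold
    report.gmm_params = bc.gmm_params
    cls = classify(tree, bc.threshold)
    pd.DataFrame(
        [{"cell_id": cid, "class": c} for cid, c in sorted(cls.per_cell_class.items())]
    ).to_csv(os.path.join(config.outdir, "cell_classes.csv"), index=False)

    # mechanism 1: stochastic switching
    try:
        seqs = switching.binarize_lineages(tree, cls)
        hmm = switching.transition_randomization_test(
            seqs, n_shuffles=config.n_shuffles, seed=seeds[3]
        )
        report.hmm_edges = hmm.edge_table()
        pd.DataFrame(report.hmm_edges).to_csv(
            os.path.join(config.outdir, "hmm_edges.csv"), index=False
        )
    except Exception as exc:  # recorded, not fatal
        report.stages_failed["switching"] = exc

    # mechanism 2: periodic oscillation
    if config.run_oscillation:
        try:
            feats, fits, excluded = oscillation.analyze_oscillation(
                tree, cls, seed=seeds[4]
            )
            report.oscillation = oscillation.compare_classes(feats)
            rows = [
                {
                    "lineage_id": f.lineage_id,
                    "class": f.cell_class,
                    "frequency_per_h": f.principal_frequency,
                    "amplitude_mM": f.principal_amplitude,
                }
                for f in feats
            ]
            pd.DataFrame(rows).to_csv(
                os.path.join(config.outdir, "oscillation_features.csv"), index=False
            )
            with open(os.path.join(config.outdir, "oscillation_excluded.txt"), "w") as fh:
                fh.write("\n".join(excluded) + ("\n" if excluded else ""))
        except Exception as exc:
            report.stages_failed["oscillation"] = exc

    # mechanism 3: cellular age
    try:
        assignments = assign_pole_ages(tree)
        report.age = compare_age_classes(assignments, cls)
        pd.DataFrame(
            [
                {"cell_id": a.cell_id, "cell_age": a.cell_age,
                 "class": cls.per_cell_class.get(a.cell_id)}
                for a in assignments
            ]
        ).to_csv(os.path.join(config.outdir, "pole_ages.csv"), index=False)
    except Exception as exc:
        report.stages_failed["age"] = exc

    # mechanism 4: intercellular transmission
    try:
        snap = transmission.final_snapshot(tree, cls)
        counts = collections.Counter(snap.classes)
        loc_p = None
        if len(counts) == 2 and min(counts.values()) >= 1:
            loc_p = transmission.spatial_localization_test(
                snap, n_perm=config.n_perm, seed=seeds[5]
            )
        sf = transmission.compute_spatial_factors(snap, tree)
        report.spatial = {
            "localization_p": loc_p,
            "ratio_spatial": {
                "mean": sf.ratio_spatial.mean, "lower": sf.ratio_spatial.lower,
                "upper": sf.ratio_spatial.upper, "reject": sf.ratio_spatial.reject_h0,
            },
            "ratio_lineage": {
                "mean": sf.ratio_lineage.mean, "lower": sf.ratio_lineage.lower,
                "upper": sf.ratio_lineage.upper, "reject": sf.ratio_lineage.reject_h0,
            },
            "n_used": sf.n_used,
        }
        pd.DataFrame(
            [dict(cell_id=cid, **rec) for cid, rec in sf.per_cell.items()]
        ).to_csv(os.path.join(config.outdir, "spatial_factors.csv"), index=False)
    except Exception as exc:
        report.stages_failed["transmission"] = exc

    # growth rate
    try:
        records = growth.division_records(tree)
        est = growth.euler_lotka_rate(records)
        report.growth_rate = {
            "Lambda": est.Lambda, "Delta": est.Delta,
            "n_lineages": est.n_lineages, "residual": est.residual,
        }
        pd.DataFrame(
            [
                {"lineage_id": r.lineage_id, "division_index": i, "tau_h": tau}
                for r in records for i, tau in enumerate(r.tau)
            ]
        ).to_csv(os.path.join(config.outdir, "division_times.csv"), index=False)
    except Exception as exc:
        report.stages_failed["growth"] = exc

    with open(os.path.join(config.outdir, "report.txt"), "w") as fh:
        fh.write(report.to_text())
    return report
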