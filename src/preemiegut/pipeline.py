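"""End-to-end drivers joining the analysis stages.

These are the entry points the command-line interface and the
reproduction script call: per-rank preprocessing plus mixed-model panels,
and the succession-timing procedure (PMA screen -> trajectories -> ED-PELT
-> cross-taxon tally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .changepoint import (
    ChangePointResult,
    ChangePointTally,
    build_trajectory,
    ed_pelt,
    penalty_elbow,
    select_taxa_for_cpa,
    tally_change_points,
)
from .cohort_stats import LmmResult, any_shcgt_indicator, bh_adjust, fit_abundance_lmm
from .compositional import preprocess
from .data_model import CountMatrix, HcgGroup, SampleRecord

__all__ = ["abundance_panel", "run_succession", "SuccessionOutput"]


def abundance_panel(
    cm: CountMatrix,
    samples: Sequence[SampleRecord],
    groups: Mapping[str, HcgGroup | int],
    rank: str,
    window: str = "overall",
    fdr: float = 0.01,
    min_total: int = 1000,
    min_mean_pct: float = 0.1,
) -> pd.DataFrame:
    """Per-taxon mixed-model contrasts (any SHCGT vs AHCGT) at one rank,
    with Benjamini-Hochberg flags; returns a tidy frame."""
    ranked, _, clr = preprocess(cm, rank, min_total=min_total, min_mean_pct=min_mean_pct)
    indicator = any_shcgt_indicator(groups)
    results: list[LmmResult] = []
    for taxon in ranked.features:
        try:
            results.append(
                fit_abundance_lmm(
                    clr.values.loc[taxon], samples, indicator, window=window, taxon=taxon
                )
            )
        except ValueError:
            continue
    flags = bh_adjust([r.p_value for r in results], fdr=fdr)
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in results],
            "window": window,
            "ls_mean_diff": [r.ls_mean_diff for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": flags.p_values,
            "q": flags.q_values,
            "significant": flags.flags,
            "marginal_r2": [r.marginal_r2 for r in results],
            "n_obs": [r.n_obs for r in results],
            "converged": [r.converged for r in results],
        }
    )


@dataclass
class SuccessionOutput:
    tally: ChangePointTally
    change_points: list[ChangePointResult]
    selected_taxa: list[str]
    lmm_results: list[LmmResult]


def run_succession(
    cm: CountMatrix,
    samples: Sequence[SampleRecord],
    groups: Mapping[str, HcgGroup | int],
    rank: str,
    fdr: float = 0.01,
    penalty: float | None = None,
    penalty_grid: Sequence[float] | None = None,
    n_quantiles: int | None = None,
    week_start: int = 24,
    week_end: int = 36,
    min_total: int = 1000,
    min_mean_pct: float = 0.1,
) -> SuccessionOutput:
    """Succession-timing procedure at one taxonomic rank.

    Taxa passing the PMA screen get a per-group weekly trajectory; each
    trajectory is segmented by ED-PELT at the elbow-selected penalty
    (or a fixed ``penalty`` override) and the change points are tallied by
    PMA week, yielding the key succession week.
    """
    ranked, pct, clr = preprocess(cm, rank, min_total=min_total, min_mean_pct=min_mean_pct)
    indicator = any_shcgt_indicator(groups)
    lmm_results = []
    for taxon in ranked.features:
        try:
            lmm_results.append(
                fit_abundance_lmm(
                    clr.values.loc[taxon],
                    samples,
                    indicator,
                    window="overall",
                    include_pma=True,
                    taxon=taxon,
                )
            )
        except ValueError:
            continue
    selected = select_taxa_for_cpa(lmm_results, fdr=fdr)
    cp_results: list[ChangePointResult] = []
    group_levels = sorted({int(g) for g in groups.values()})
    for taxon in selected:
        for g in group_levels:
            traj = build_trajectory(
                pct, taxon, g, samples, groups, week_start=week_start, week_end=week_end
            )
            if traj is None:
                continue
            if penalty is None:
                path = penalty_elbow(traj.values, penalty_grid, n_quantiles)
                pen = path.selected_penalty
            else:
                pen = penalty
            cps = ed_pelt(traj.values, pen, n_quantiles)
            cp_results.append(
                ChangePointResult(
                    taxon=taxon, group=g, penalty=pen, change_points=cps, weeks=traj.weeks
                )
            )
    tally = tally_change_points(cp_results, rank, week_start=week_start, week_end=week_end)
    return SuccessionOutput(tally, cp_results, selected, lmm_results)
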