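"""Genomic-instability indices and survival association.

Instability measures per sample: counts of fused gain/loss/high-gain runs,
raw segment count, fraction of the covered genome gained/lost/high-gained,
and transition-count ("Hicks-style") indices.  Survival association uses Cox
proportional-hazards fits (delegated to lifelines) per covariate, with BH
correction across each covariate family; OS and PFS are run separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import bh_adjust
from .genome_io import CopyNumberProfile
from .preprocess import CallThresholds, call_states

INSTABILITY_COLUMNS = (
    "n_gain", "n_loss", "n_highgain", "n_segments",
    "pct_gain", "pct_loss", "pct_highgain",
    "hicks_gain", "hicks_loss", "hicks_total",
)


@dataclass
class InstabilityProfile:
    sample_id: str
    n_gain: int
    n_loss: int
    n_highgain: int
    n_segments: int
    pct_gain: float
    pct_loss: float
    pct_highgain: float
    hicks_gain: int
    hicks_loss: int
    hicks_total: int


def _count_runs(
    flags: list[bool], boundaries: list[bool], highs: list[bool] | None = None
) -> tuple[int, int]:
    """Count maximal runs of True, where a True at a chromosome boundary (or
    after a False) starts a new run.  Also counts the runs containing at
    least one high-flagged segment, so high runs nest inside plain runs by
    construction.  Returns (runs, high_runs)."""
    if highs is None:
        highs = [False] * len(flags)
    runs = high_runs = 0
    in_run = run_high = False

    def close():
        nonlocal high_runs, in_run, run_high
        if in_run and run_high:
            high_runs += 1
        in_run = run_high = False

    for flag, new_chrom, high in zip(flags, boundaries, highs):
        if not flag or new_chrom:
            close()
        if flag:
            if not in_run:
                runs += 1
                in_run = True
            run_high = run_high or high
    close()
    return runs, high_runs


def instability_measures(
    profile: CopyNumberProfile, thresholds: CallThresholds | None = None
) -> InstabilityProfile:
    """Per-sample instability summary.

    Counts are of fused maximal runs: adjacent same-state segments count once,
    so splitting a segment in two identical halves changes nothing.  The
    transition indices count steps between consecutive segments whose log2
    jump exceeds the call threshold - upward steps for gains, downward for
    losses, and their sum in total.
    """
    thresholds = thresholds or CallThresholds()
    calls = call_states(profile, thresholds)
    segs = profile.segments
    high_cut = thresholds.high_tiers[0]

    new_chrom = [
        i == 0 or segs[i].chrom != segs[i - 1].chrom for i in range(len(segs))
    ]
    gain_flags = [c.state == "gain" for c in calls]
    loss_flags = [c.state == "loss" for c in calls]
    high_flags = [s.log2 > high_cut for s in segs]

    total_len = sum(s.length for s in segs)
    gain_len = sum(s.length for s, f in zip(segs, gain_flags) if f)
    loss_len = sum(s.length for s, f in zip(segs, loss_flags) if f)
    high_len = sum(s.length for s, f in zip(segs, high_flags) if f)

    hicks_gain = hicks_loss = 0
    for i in range(1, len(segs)):
        if new_chrom[i]:
            continue
        delta = segs[i].log2 - segs[i - 1].log2
        if delta > thresholds.gain:
            hicks_gain += 1
        elif delta < thresholds.loss:
            hicks_loss += 1

    n_gain, n_highgain = _count_runs(gain_flags, new_chrom, high_flags)
    n_loss, _ = _count_runs(loss_flags, new_chrom)
    return InstabilityProfile(
        sample_id=profile.sample_id,
        n_gain=n_gain,
        n_loss=n_loss,
        n_highgain=n_highgain,
        n_segments=len(segs),
        pct_gain=gain_len / total_len if total_len else 0.0,
        pct_loss=loss_len / total_len if total_len else 0.0,
        pct_highgain=high_len / total_len if total_len else 0.0,
        hicks_gain=hicks_gain,
        hicks_loss=hicks_loss,
        hicks_total=hicks_gain + hicks_loss,
    )


def instability_table(
    profiles: Sequence[CopyNumberProfile],
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    rows = [vars(instability_measures(p, thresholds)) for p in profiles]
    return pd.DataFrame(rows).set_index("sample_id")


def quartile_bin(values: Sequence[float]) -> np.ndarray:
    """Bin values into groups 1-4 at the empirical 25/50/75 percentiles;
    ties go to the lower group."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples to form quartiles")
    if np.ptp(x) == 0:
        raise ValueError("no quartile structure in a constant vector")
    cuts = np.quantile(x, [0.25, 0.5, 0.75])
    groups = np.ones(x.size, dtype=int)
    for cut in cuts:
        groups += x > cut
    return groups


@dataclass
class SurvivalAssociation:
    covariate: str
    grouping: str  # binary | pair_groups | quartiles
    hazard_ratios: dict
    p: float
    q: float = np.nan
    flagged: str = ""


def pair_groups(status_a: Sequence[int], status_b: Sequence[int]) -> np.ndarray:
    """Four-group coding of a region pair: 1=neither, 2=A only, 3=B only, 4=both."""
    a = np.asarray(status_a, dtype=int)
    b = np.asarray(status_b, dtype=int)
    return 1 + a + 2 * b


def _fit_cox(
    groups: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[dict, float, str]:
    """Cox PH on group labels: binary groups use the 0/1 covariate directly;
    multi-level groups are dummy-coded against the lowest label.  Returns
    (hazard ratios vs reference, p, flag)."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    for level in levels:
        if events[groups == level].sum() == 0:
            return {}, np.nan, f"no events in group {level}"
    df = pd.DataFrame({"time": times, "event": events})
    if levels.size == 2:
        df["x"] = (groups == levels[1]).astype(float)
        cols = ["x"]
        names = {str(levels[1]): "x"}
    else:
        cols = []
        names = {}
        for level in levels[1:]:
            col = f"g{level}"
            df[col] = (groups == level).astype(float)
            cols.append(col)
            names[str(level)] = col
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return {}, np.nan, "separation"
    hrs = {
        f"{level}_vs_{levels[0]}": float(np.exp(cph.params_[col]))
        for level, col in names.items()
    }
    if levels.size == 2:
        p = float(cph.summary.loc["x", "p"])  # Wald p on the single coefficient
    else:
        p = float(cph.log_likelihood_ratio_test().p_value)
    return hrs, p, ""


def survival_assoc(
    covariates: pd.DataFrame,
    survival: pd.DataFrame,
    family: str,
    grouping: str = "binary",
) -> list[SurvivalAssociation]:
    """Proportional-hazards association for each covariate column.

    ``covariates`` holds group labels per sample (binary region status,
    four pair groups, or quartile labels); ``survival`` has 'time' and
    'event' columns on the same index.  BH is applied across the family.
    """
    shared = covariates.index.intersection(survival.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between covariates and survival")
    cov = covariates.loc[shared]
    surv = survival.loc[shared]
    times = surv["time"].to_numpy(dtype=float)
    events = surv["event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("no events in the survival data")
    results: list[SurvivalAssociation] = []
    for name in cov.columns:
        groups = cov[name].to_numpy()
        hrs, p, flag = _fit_cox(groups, times, events)
        results.append(
            SurvivalAssociation(
                covariate=f"{family}:{name}",
                grouping=grouping,
                hazard_ratios=hrs,
                p=p,
                flagged=flag,
            )
        )
    usable = [r for r in results if np.isfinite(r.p)]
    if usable:
        q = bh_adjust([r.p for r in usable])
        for r, qv in zip(usable, q):
            r.q = float(qv)
    return results


def survival_to_frame(results: Sequence[SurvivalAssociation]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "covariate": r.covariate,
                "grouping": r.grouping,
                "hazard_ratios": ";".join(
                    f"{k}={v:.4g}" for k, v in r.hazard_ratios.items()
                ),
                "p": r.p,
                "q": r.q,
                "flagged": r.flagged,
            }
        )
    return pd.DataFrame(rows)
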