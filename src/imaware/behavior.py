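"""Session construction, response categorization and detection performance.

A session holds 240 ten-second trials in 4 blocks of 60; the target is present
in two thirds of them (160:80), balanced over the four masker-density levels.
Responses are scored as hit / miss / false alarm / correct rejection; a
key press earlier than 1600 ms cannot reflect two heard target repetitions
and is dismissed as a guess.  Sensitivity is d' = z(HR) - z(FAR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stimgen import DENSITY_PAIRS

GUESS_CUTOFF_S = 1.6
N_TRIALS = 240
N_BLOCKS = 4
TARGET_PRESENT_FRACTION = 2 / 3


@dataclass
class TrialRecord:
    subject: str
    block: int                 # 1..4
    trial: int                 # index within session
    target_present: bool
    density_label: int         # {11, 20, 28, 36}
    response_time: float | None = None  # s, or None when no press
    trial_duration: float = 10.0


def build_session(rng: np.random.Generator | None = None,
                  subject: str = "S01") -> list[TrialRecord]:
    """Build the 240-trial session.

    160 target-present / 80 target-absent trials, each density level used on
    exactly 40 present and 20 absent trials, shuffled and cut into 4 blocks
    of 60.  The composition is exact, not in expectation.
    """
    if rng is None:
        rng = np.random.default_rng()
    densities = sorted(DENSITY_PAIRS)
    cells = [(True, d) for d in densities for _ in range(40)]
    cells += [(False, d) for d in densities for _ in range(20)]
    order = rng.permutation(len(cells))
    trials = []
    for i, j in enumerate(order):
        present, density = cells[j]
        trials.append(TrialRecord(subject=subject, block=i // 60 + 1, trial=i,
                                  target_present=present, density_label=density))
    return trials


def categorize_trial(t: TrialRecord, guess_cutoff: float = GUESS_CUTOFF_S,
                     drop_guesses: bool = False) -> str | None:
    """Assign one of {hit, miss, false_alarm, correct_rejection}.

    A target-present press earlier than ``guess_cutoff`` is a guess; by
    default it is recoded as a miss so every trial lands in one category.
    With ``drop_guesses=True`` such trials are excluded (returns None).
    """
    if t.target_present:
        if t.response_time is None:
            return "miss"
        if t.response_time >= guess_cutoff:
            return "hit"
        return None if drop_guesses else "miss"
    return "false_alarm" if t.response_time is not None else "correct_rejection"


def outcome_counts(trials: list[TrialRecord], guess_cutoff: float = GUESS_CUTOFF_S,
                   drop_guesses: bool = False) -> dict:
    counts = {"hit": 0, "miss": 0, "false_alarm": 0, "correct_rejection": 0}
    for t in trials:
        cat = categorize_trial(t, guess_cutoff, drop_guesses)
        if cat is not None:
            counts[cat] += 1
    return counts


def rates(counts: dict, correction: str = "loglinear") -> tuple[float, float]:
    """Hit and false-alarm rates with an optional extreme-rate correction.

    ``loglinear`` adds 0.5 to each cell and 1 to each denominator, keeping
    rates off 0 and 1; ``none`` returns raw proportions.
    """
    h, m = counts["hit"], counts["miss"]
    fa, cr = counts["false_alarm"], counts["correct_rejection"]
    if correction == "loglinear":
        hr = (h + 0.5) / (h + m + 1.0)
        far = (fa + 0.5) / (fa + cr + 1.0)
    elif correction == "none":
        hr = h / (h + m) if h + m else np.nan
        far = fa / (fa + cr) if fa + cr else np.nan
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return hr, far


def dprime(hr: float, far: float) -> float:
    """d' = z(HR) - z(FAR) with z the inverse standard-normal CDF."""
    if not (0.0 <= hr <= 1.0 and 0.0 <= far <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    z_hr, z_far = norm.ppf(hr), norm.ppf(far)
    if not np.isfinite(z_hr) or not np.isfinite(z_far):
        raise ValueError("extreme rate (0 or 1): apply a correction first")
    return float(z_hr - z_far)


def dprime_from_counts(counts: dict, correction: str = "loglinear") -> float:
    return dprime(*rates(counts, correction))


def score_table(df: pd.DataFrame, guess_cutoff: float = GUESS_CUTOFF_S,
                drop_guesses: bool = False) -> pd.DataFrame:
    """Categorize a trial/response table.

    Expects columns subject, block, trial, target_present, density,
    response_time_s (NaN = no press); returns the table with an added
    ``outcome`` column (guess-dropped trials removed).
    """
    out = df.copy()
    cats = []
    for _, row in out.iterrows():
        rt = row["response_time_s"]
        rec = TrialRecord(subject=row["subject"], block=int(row["block"]),
                          trial=int(row["trial"]),
                          target_present=bool(row["target_present"]),
                          density_label=int(row["density"]),
                          response_time=None if pd.isna(rt) else float(rt))
        cats.append(categorize_trial(rec, guess_cutoff, drop_guesses))
    out["outcome"] = cats
    return out[out["outcome"].notna()]


def dprime_by_density(scored: pd.DataFrame, correction: str = "loglinear") -> pd.DataFrame:
    """One d' per (subject, density) plus a per-density group summary.

    ``scored`` is the output of :func:`score_table`.  False alarms are
    attributed to the density of the trial they occurred on (every trial
    carries a masker density).
    """
    rows = []
    for (subj, dens), grp in scored.groupby(["subject", "density"]):
        counts = {k: int((grp["outcome"] == k).sum())
                  for k in ("hit", "miss", "false_alarm", "correct_rejection")}
        if counts["hit"] + counts["miss"] == 0:
            import warnings
            warnings.warn(f"no target-present trials for subject={subj} density={dens}")
            d = np.nan
        else:
            d = dprime_from_counts(counts, correction)
        rows.append({"subject": subj, "density": dens, "dprime": d, **counts})
    return pd.DataFrame(rows)


def dprime_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Group mean and SD of d' per density."""
    return (per_subject.groupby("density")["dprime"]
            .agg(["mean", "std", "count"]).reset_index())


def simulate_responses(trials: list[TrialRecord], rng: np.random.Generator,
                       hit_rate_by_density: dict[int, float] | None = None,
                       fa_rate: float = 0.11,
                       rt_mean: float = 3.45, rt_sd: float = 1.58) -> pd.DataFrame:
    """Simulate key presses for a built session (for demos and tests).

    Hits occur with a density-dependent probability (default: the group mean
    0.71 at every density) at truncated-normal latencies above the guess
    cutoff; false alarms occur at ``fa_rate`` on target-absent trials.
    """
    if hit_rate_by_density is None:
        hit_rate_by_density = {d: 0.71 for d in DENSITY_PAIRS}
    rows = []
    for t in trials:
        rt = np.nan
        p = hit_rate_by_density[t.density_label] if t.target_present else fa_rate
        if rng.uniform() < p:
            while True:
                cand = rng.normal(rt_mean, rt_sd)
                if GUESS_CUTOFF_S < cand <= t.trial_duration:
                    rt = cand
                    break
        rows.append({"subject": t.subject, "block": t.block, "trial": t.trial,
                     "target_present": t.target_present,
                     "density": t.density_label, "response_time_s": rt})
    return pd.DataFrame(rows)
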