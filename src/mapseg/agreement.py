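"""Scaled segmentation agreement and its null/specificity tests.

A participant's press times on one stimulus are debounced (presses within
500 ms of the last retained press are dropped), binned into 1-second bins,
and correlated with the leave-one-out group norm (the proportion of the
other participants pressing in each bin). Because the Pearson correlation
of a binary vector with a fixed norm is bounded by the placements of its k
ones on the k largest / smallest norm values, the observed correlation is
rescaled to

    agreement = (r_obs - r_min) / (r_max - r_min)    in [0, 1].

Chance level is assessed with a permutation null: each trial's binned
series is independently re-timed (permuted), keeping press counts fixed,
and the sample-mean agreement recomputed; specificity is assessed against
cross-stimulus and cross-group norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .responses import ResponseLog

__all__ = [
    "BinnedResponse",
    "GroupNorm",
    "AgreementRecord",
    "NullDistribution",
    "DegenerateAgreementError",
    "debounce",
    "bin_presses",
    "group_norm",
    "correlation_bounds",
    "scaled_agreement",
    "unit_durations",
    "filter_trials",
    "bin_cohort",
    "agreement_table",
    "permutation_null",
    "two_tailed_p",
    "specificity_table",
]

DEBOUNCE_WINDOW_S = 0.5


class DegenerateAgreementError(ValueError):
    """Raised when agreement is undefined (k in {0, n} or a constant norm)."""


@dataclass(frozen=True)
class BinnedResponse:
    bins: np.ndarray  # binary, length duration_s

    def __post_init__(self):
        b = np.asarray(self.bins)
        if not np.isin(b, (0, 1)).all():
            raise ValueError("bins must be binary")
        object.__setattr__(self, "bins", b.astype(np.int8))

    @property
    def k(self) -> int:
        return int(self.bins.sum())


@dataclass(frozen=True)
class GroupNorm:
    proportions: np.ndarray  # per-bin proportion of the other participants
    n_others: int

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if p.min() < 0 or p.max() > 1:
            raise ValueError("proportions must lie in [0, 1]")
        object.__setattr__(self, "proportions", p)


@dataclass(frozen=True)
class AgreementRecord:
    participant_id: str
    stimulus_id: str
    comparison: str  # same_stimulus | cross_stimulus | own_group | other_group
    comparison_target: str
    r_obs: float
    r_min: float
    r_max: float
    agreement: float
    group: str = ""


@dataclass(frozen=True)
class NullDistribution:
    samples: np.ndarray  # per-iteration mean sample agreement

    @property
    def iterations(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1))

    @property
    def q2_5(self) -> float:
        return float(np.quantile(self.samples, 0.025))

    @property
    def q97_5(self) -> float:
        return float(np.quantile(self.samples, 0.975))

    def summary(self) -> dict:
        return {"iterations": self.iterations, "mean": self.mean, "sd": self.sd,
                "q2.5": self.q2_5, "q97.5": self.q97_5}


# ---------------------------------------------------------------------------
# Per-trial primitives
# ---------------------------------------------------------------------------


def debounce(press_times, window_s: float = DEBOUNCE_WINDOW_S) -> list[float]:
    """Greedy left-to-right debouncing relative to the last *retained* press."""
    times = list(press_times)
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("press times must be sorted ascending")
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= window_s:
            kept.append(float(t))
    return kept


def bin_presses(press_times, duration_s: int) -> BinnedResponse:
    """Half-open 1-second bins [b, b+1); t == duration clamps to the last bin."""
    bins = np.zeros(duration_s, dtype=np.int8)
    for t in press_times:
        if t < 0:
            raise ValueError("negative press time")
        if t > duration_s:
            raise ValueError("press after the video end must be excluded upstream")
        bins[min(int(np.floor(t)), duration_s - 1)] = 1
    return BinnedResponse(bins=bins)


def group_norm(binned_matrix: np.ndarray, exclude_idx: int) -> GroupNorm:
    """Per-bin proportion over all rows except ``exclude_idx``."""
    m = np.asarray(binned_matrix, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("group norm needs at least 2 participants")
    mask = np.ones(m.shape[0], dtype=bool)
    mask[exclude_idx] = False
    return GroupNorm(proportions=m[mask].mean(axis=0), n_others=int(mask.sum()))


def _corr_from_selection(sel_sum: float, k: int, norm: np.ndarray) -> float:
    """Pearson r of a k-ones indicator (with selected-norm sum ``sel_sum``)."""
    n = len(norm)
    cov = sel_sum - k * norm.mean()
    sx = np.sqrt(k * (1.0 - k / n))
    sm = np.sqrt(np.sum((norm - norm.mean()) ** 2))
    return float(cov / (sx * sm))


def correlation_bounds(k: int, norm: GroupNorm) -> tuple[float, float]:
    """Extreme correlations attainable with k one-bins against ``norm``.

    r_max places the ones on the k largest norm values, r_min on the k
    smallest (ties broken by earliest bin); the correlation is monotone in
    the selected-norm sum, so these are the exact combinatorial extremes.
    """
    p = norm.proportions
    n = len(p)
    if not 0 < k < n:
        raise DegenerateAgreementError(f"k={k} leaves no free placement in {n} bins")
    if np.ptp(p) < 1e-15:
        raise DegenerateAgreementError("constant group norm has zero variance")
    top = np.argsort(-p, kind="stable")[:k]
    bot = np.argsort(p, kind="stable")[:k]
    r_max = _corr_from_selection(float(p[top].sum()), k, p)
    r_min = _corr_from_selection(float(p[bot].sum()), k, p)
    return r_min, r_max


def scaled_agreement(binned: BinnedResponse, norm: GroupNorm,
                     participant_id: str = "", stimulus_id: str = "",
                     comparison: str = "same_stimulus",
                     comparison_target: str = "", group: str = "") -> AgreementRecord:
    """Scaled agreement (r_obs - r_min) / (r_max - r_min) for one trial."""
    r_min, r_max = correlation_bounds(binned.k, norm)
    if r_max - r_min < 1e-12:
        raise DegenerateAgreementError("r_max equals r_min; agreement undefined")
    p = norm.proportions
    sel = float(p[binned.bins.astype(bool)].sum())
    r_obs = _corr_from_selection(sel, binned.k, p)
    agreement = (r_obs - r_min) / (r_max - r_min)
    return AgreementRecord(
        participant_id=participant_id, stimulus_id=stimulus_id,
        comparison=comparison,
        comparison_target=comparison_target or stimulus_id,
        r_obs=r_obs, r_min=r_min, r_max=r_max,
        agreement=float(np.clip(agreement, 0.0, 1.0)), group=group)


def unit_durations(press_times, duration_s: float) -> list[float]:
    """Durations of the event units delimited by 0, the presses, and the end."""
    bounds = [0.0, *[float(t) for t in press_times], float(duration_s)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# Cohort-level assembly
# ---------------------------------------------------------------------------


def filter_trials(logs: list[ResponseLog],
                  duration_by_stimulus: dict[str, int]) -> tuple[list[ResponseLog], dict]:
    """Drop empty trials and trials with post-end presses; account for both."""
    kept, n_empty, n_postend = [], 0, 0
    for log in logs:
        dur = duration_by_stimulus[log.stimulus_id]
        if not log.press_times_s:
            n_empty += 1
        elif max(log.press_times_s) > dur:
            n_postend += 1
        else:
            kept.append(log)
    audit = {"total": len(logs), "empty": n_empty, "post_end": n_postend,
             "retained": len(kept)}
    assert audit["retained"] + n_empty + n_postend == audit["total"]
    return kept, audit


def bin_cohort(logs: list[ResponseLog], duration_by_stimulus: dict[str, int],
               window_s: float = DEBOUNCE_WINDOW_S):
    """Filter, debounce and bin a cohort.

    Returns ``(binned, audit)`` where ``binned`` maps (group, stimulus_id)
    to an ordered dict participant_id -> binary vector, and the audit counts
    every exclusion (empty, post-end, all-bins-set).
    """
    kept, audit = filter_trials(logs, duration_by_stimulus)
    binned: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    n_saturated = 0
    for log in kept:
        dur = duration_by_stimulus[log.stimulus_id]
        b = bin_presses(debounce(log.press_times_s, window_s), dur)
        if b.k == dur:  # all bins set: bounds undefined
            n_saturated += 1
            continue
        binned.setdefault((log.group, log.stimulus_id), {})[log.participant_id] = b.bins
    audit = {**audit, "saturated": n_saturated,
             "analyzable": audit["retained"] - n_saturated}
    return binned, audit


def _matrix_agreements(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row scaled agreement against leave-one-out norms.

    B is a (participants x bins) binary matrix for one (group, stimulus).
    Returns (agreements, valid) where invalid rows (degenerate bounds or a
    constant norm) carry NaN.
    """
    B = np.asarray(B, dtype=float)
    P, n = B.shape
    k = B.sum(axis=1)
    norms = (B.sum(axis=0)[None, :] - B) / (P - 1)  # (P, n) LOO norms
    nbar = norms.mean(axis=1)
    sm = np.sqrt(np.sum((norms - nbar[:, None]) ** 2, axis=1))
    sx = np.sqrt(k * (1.0 - k / n))
    valid = (k > 0) & (k < n) & (sm > 1e-12)

    sel = np.einsum("ij,ij->i", B, norms)
    r_obs = (sel - k * nbar) / np.where(valid, sx * sm, np.nan)

    srt = np.sort(norms, axis=1)  # ascending
    csum = np.cumsum(srt, axis=1)
    kk = np.clip(k.astype(int), 1, n - 1)
    bot = np.take_along_axis(csum, (kk - 1)[:, None], axis=1)[:, 0]
    total = csum[:, -1]
    top = total - np.take_along_axis(csum, (n - kk - 1)[:, None], axis=1)[:, 0]
    r_min = (bot - k * nbar) / np.where(valid, sx * sm, np.nan)
    r_max = (top - k * nbar) / np.where(valid, sx * sm, np.nan)
    denom = r_max - r_min
    valid = valid & (denom > 1e-12)
    agree = np.where(valid, np.clip((r_obs - r_min) / np.where(valid, denom, np.nan),
                                    0.0, 1.0), np.nan)
    return agree, valid


def agreement_table(binned: dict[tuple[str, str], dict[str, np.ndarray]]) -> pd.DataFrame:
    """Same-stimulus agreement records for a binned cohort, one row per trial.

    Norms are leave-one-out within the trial's experimental group. Trials
    whose bounds are degenerate are returned with NaN agreement so callers
    can account for them explicitly.
    """
    rows = []
    for (group, stim), trials in sorted(binned.items()):
        pids = list(trials)
        if len(pids) < 2:
            continue
        B = np.vstack([trials[p] for p in pids])
        agree, valid = _matrix_agreements(B)
        for i, pid in enumerate(pids):
            rows.append({"participant_id": pid, "stimulus_id": stim,
                         "group": group, "comparison": "same_stimulus",
                         "comparison_target": stim,
                         "n_presses": int(B[i].sum()),
                         "agreement": float(agree[i]) if valid[i] else np.nan})
    return pd.DataFrame(rows)


def permutation_null(binned: dict[tuple[str, str], dict[str, np.ndarray]],
                     iterations: int = 10_000, seed: int = 0) -> NullDistribution:
    """Null distribution of the mean sample agreement under random re-timing.

    Each iteration independently permutes every trial's binned series
    (press counts preserved), recomputes all leave-one-out agreements from
    the permuted data, and records the mean across trials.
    """
    mats = [np.vstack(list(trials.values()))
            for _, trials in sorted(binned.items()) if len(trials) >= 2]
    if not mats:
        raise ValueError("no stimulus has >= 2 analyzable trials")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 21])
    samples = np.empty(iterations)
    for it in range(iterations):
        total, count = 0.0, 0
        for B in mats:
            P, n = B.shape
            perm = rng.random((P, n)).argsort(axis=1)
            Bp = np.take_along_axis(B, perm, axis=1)
            agree, valid = _matrix_agreements(Bp)
            total += np.nansum(agree)
            count += int(valid.sum())
        samples[it] = total / count if count else np.nan
    return NullDistribution(samples=samples)


def two_tailed_p(null: NullDistribution, observed_mean: float) -> float:
    """Symmetric two-tailed permutation p with add-one smoothing per tail."""
    x = null.samples
    d = abs(observed_mean - null.mean)
    n_le = int(np.sum(x <= null.mean - d))
    n_ge = int(np.sum(x >= null.mean + d))
    return min(1.0, (n_le + n_ge + 2) / (null.iterations + 1))


def specificity_table(binned: dict[tuple[str, str], dict[str, np.ndarray]],
                      mode: str = "cross_stimulus") -> pd.DataFrame:
    """Same-stimulus records plus cross-stimulus or cross-group baselines.

    ``cross_stimulus``: each trial is additionally scored against the norm
    of every *other* stimulus within the participant's group (leave-one-out
    with respect to the participant, applied uniformly). ``cross_group``:
    each trial is scored against its own-group leave-one-out norm and the
    full norm of the other group.
    """
    if mode not in ("cross_stimulus", "cross_group"):
        raise ValueError("mode must be cross_stimulus or cross_group")
    rows: list[dict] = []

    def score(bins: np.ndarray, norm_vec: np.ndarray, n_others: int):
        b = BinnedResponse(bins=bins)
        try:
            rec = scaled_agreement(b, GroupNorm(norm_vec, n_others))
            return rec.agreement
        except DegenerateAgreementError:
            return np.nan

    if mode == "cross_stimulus":
        by_group: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        for (group, stim), trials in binned.items():
            by_group.setdefault(group, {})[stim] = trials
        for group, stims in sorted(by_group.items()):
            durations = {s: len(next(iter(t.values()))) for s, t in stims.items()}
            if len(set(durations.values())) > 1:
                raise ValueError("cross-stimulus contrasts need equal durations")
            for stim, trials in sorted(stims.items()):
                pids = list(trials)
                if len(pids) < 2:
                    continue
                B = np.vstack([trials[p] for p in pids])
                agree, valid = _matrix_agreements(B)
                for i, pid in enumerate(pids):
                    rows.append({"participant_id": pid, "stimulus_id": stim,
                                 "group": group, "comparison": "same_stimulus",
                                 "comparison_target": stim,
                                 "agreement": float(agree[i]) if valid[i] else np.nan})
                    for other, otrials in sorted(stims.items()):
                        if other == stim:
                            continue
                        opids = [q for q in otrials if q != pid]
                        if len(opids) < 1:
                            continue
                        norm_vec = np.mean([otrials[q] for q in opids], axis=0)
                        rows.append({"participant_id": pid, "stimulus_id": stim,
                                     "group": group, "comparison": "cross_stimulus",
                                     "comparison_target": other,
                                     "agreement": score(B[i], norm_vec, len(opids))})
    else:
        groups = sorted({g for g, _ in binned})
        if len(groups) != 2:
            raise ValueError("cross_group needs exactly 2 groups")
        for (group, stim), trials in sorted(binned.items()):
            other_group = groups[1] if group == groups[0] else groups[0]
            pids = list(trials)
            if len(pids) < 2:
                continue
            B = np.vstack([trials[p] for p in pids])
            agree, valid = _matrix_agreements(B)
            otrials = binned.get((other_group, stim), {})
            onorm = (np.mean(list(otrials.values()), axis=0)
                     if otrials else None)
            for i, pid in enumerate(pids):
                rows.append({"participant_id": pid, "stimulus_id": stim,
                             "group": group, "comparison": "own_group",
                             "comparison_target": group,
                             "agreement": float(agree[i]) if valid[i] else np.nan})
                if onorm is not None:
                    rows.append({"participant_id": pid, "stimulus_id": stim,
                                 "group": group, "comparison": "other_group",
                                 "comparison_target": other_group,
                                 "agreement": score(B[i], onorm, len(otrials))})
    return pd.DataFrame(rows)
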