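"""Effect functions and probe-wise Bayesian FDR from a fitted model.

Four analysis modes mirror the questions a tiling experiment can ask:

``compare``
    Fitted mean difference between two groups / time points (any design with
    replicated conditions).
``means``
    Fitted expression level of a single group or time point, for
    annotation-free transcript discovery.
``effects``
    A single polynomial coefficient function of a time-course design
    (linear, quadratic, ...) on the original, de-normalized coding, so the
    fitted effect at probe t is beta_d(t) * time^d.
``circadian``
    The first-harmonic amplitude A(t) = sqrt(beta_sin^2(t) + beta_cos^2(t)).

Each probe's effect is compared with a threshold delta through its posterior:
the local statistic is the posterior probability of a *false* call,
P(F beta(t) < delta | Y) for overexpression (or the mirrored form for
underexpression), and significance is declared by the direct-posterior-
probability Bayesian FDR rule: sort the local probabilities ascending and
keep the largest prefix whose running mean stays below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, SelectionError
from .fit import WaveletFit, combination_weights, effect_combination
from . import wavelet

__all__ = [
    "EffectTrack",
    "FdrTrack",
    "pairwise_contrasts",
    "effect_track",
    "fdr_track",
    "circadian_fdr",
]


@dataclass
class EffectTrack:
    """Probe-wise posterior summary of one effect function F beta(t)."""

    mode: str
    label: str
    mean: np.ndarray
    sd: np.ndarray
    side: str = "above"
    # circadian only: posterior means/sds of the sine and cosine components,
    # kept for Monte-Carlo tail probabilities of the (non-linear) amplitude
    components: Optional[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise SelectionError("mean and sd tracks must have equal length")
        if np.any(self.sd < 0):
            raise SelectionError("sd track must be nonnegative")

    @property
    def n_probes(self) -> int:
        return self.mean.size


@dataclass
class FdrTrack:
    """Local false-call probabilities and the Bayesian-FDR significance mask."""

    local_prob: np.ndarray
    significant: np.ndarray
    alpha: float
    label: str = ""
    n_sim: Optional[int] = None
    seed: Optional[int] = None


def pairwise_contrasts(q: int, group_sizes: Sequence[int]) -> np.ndarray:
    """All q(q-1)/2 pairwise group-mean contrasts as rows over the N arrays.

    Row (a, b), a < b, averages the group-a arrays (+1/N_a) against the
    group-b arrays (-1/N_b); applied to the data or the fitted values X B it
    evaluates the mean-difference function of that pair.
    """
    if q < 2:
        raise SelectionError(f"pairwise contrasts need q >= 2 groups, got {q}")
    sizes = np.asarray(group_sizes, dtype=int)
    if sizes.size != q or np.any(sizes < 1):
        raise SelectionError("group_sizes must list a positive count per group")
    n = int(sizes.sum())
    starts = np.concatenate([[0], np.cumsum(sizes)])
    rows = []
    for a in range(q):
        for bgrp in range(a + 1, q):
            z = np.zeros(n)
            z[starts[a] : starts[a + 1]] = 1.0 / sizes[a]
            z[starts[bgrp] : starts[bgrp + 1]] = -1.0 / sizes[bgrp]
            rows.append(z)
    return np.vstack(rows)


def _group_row(fit: WaveletFit, group: int) -> np.ndarray:
    """Original-coding design row of (any array in) a replicated condition."""
    design = fit.design
    if design.row_groups is None:
        raise SelectionError(f"{design.kind} design has no replicated-condition structure")
    hits = np.nonzero(design.row_groups == group)[0]
    if hits.size == 0:
        raise SelectionError(f"group index {group} out of range")
    return design.original[hits[0]]


def _pair_label(fit: WaveletFit, a: int, b: int) -> str:
    if fit.design.times is not None:
        uniq = np.unique(fit.design.times)
        return f"t{uniq[a]:g} vs t{uniq[b]:g}"
    return f"group{a} vs group{b}"


def effect_track(
    fit: WaveletFit,
    mode: str,
    selector: Union[int, tuple[int, int], None] = None,
) -> EffectTrack:
    """Build the probe-wise effect function for one analysis question.

    ``selector``: pair ``(a, b)`` or flat pair index for ``compare``; group /
    time-point index for ``means``; polynomial degree for ``effects``; ignored
    for ``circadian``.
    """
    if mode == "compare":
        if fit.design.row_groups is None:
            raise SelectionError("compare mode needs a design with replicated conditions")
        n_groups = int(fit.design.row_groups.max()) + 1
        if isinstance(selector, tuple):
            a, b = selector
        else:
            if selector is None:
                raise SelectionError("compare mode needs a pair selector")
            pairs = [(i, j) for i in range(n_groups) for j in range(i + 1, n_groups)]
            if not 0 <= int(selector) < len(pairs):
                raise SelectionError(
                    f"pair index {selector} out of range for {len(pairs)} pairs"
                )
            a, b = pairs[int(selector)]
        if not (0 <= a < n_groups and 0 <= b < n_groups and a != b):
            raise SelectionError(f"invalid group pair ({a}, {b})")
        f = _group_row(fit, a) - _group_row(fit, b)
        mean, var = effect_combination(fit, f)
        return EffectTrack("compare", _pair_label(fit, a, b), mean, np.sqrt(var))

    if mode == "means":
        if selector is None:
            raise SelectionError("means mode needs a group / time-point selector")
        f = _group_row(fit, int(selector))
        mean, var = effect_combination(fit, f)
        return EffectTrack("means", f"group{int(selector)} mean", mean, np.sqrt(var))

    if mode == "effects":
        degree = int(selector) if selector is not None else 1
        role = f"poly_degree_{degree}"
        if role not in fit.design.column_roles:
            raise SelectionError(
                f"design has no degree-{degree} polynomial effect (roles: {fit.design.column_roles})"
            )
        m = fit.design.column_roles.index(role)
        f = np.zeros(fit.q)
        f[m] = 1.0
        mean, var = effect_combination(fit, f)
        label = {1: "linear", 2: "quadratic", 3: "cubic"}.get(degree, f"degree-{degree}")
        return EffectTrack("effects", label, mean, np.sqrt(var))

    if mode == "circadian":
        roles = fit.design.column_roles
        if "sine" not in roles or "cosine" not in roles:
            raise SelectionError("circadian mode requires a Fourier (sine/cosine) design")
        tracks = []
        for role in ("sine", "cosine"):
            f = np.zeros(fit.q)
            f[roles.index(role)] = 1.0
            m, v = effect_combination(fit, f)
            tracks.extend([m, np.sqrt(v)])
        sin_m, sin_sd, cos_m, cos_sd = tracks
        amp = np.hypot(sin_m, cos_m)
        # delta-method sd, reported for plotting; FDR uses the Monte-Carlo path
        denom = np.maximum(amp, 1e-12)
        sd = np.sqrt((sin_m * sin_sd) ** 2 + (cos_m * cos_sd) ** 2) / denom
        return EffectTrack(
            "circadian", "amplitude", amp, sd, components=(sin_m, sin_sd, cos_m, cos_sd)
        )

    raise SelectionError(f"unknown inference mode {mode!r}")


def _bayes_fdr_mask(local_prob: np.ndarray, alpha: float) -> np.ndarray:
    """Direct-posterior-probability rule: largest prefix of the ascending
    local probabilities whose running mean stays <= alpha.

    The declared set is a *threshold* set {t : p_t <= kappa}: probes with
    identical local probabilities enter or leave together, so the prefix may
    only end at a tie-group boundary. For distinct probabilities this is
    exactly the plain prefix rule; with degenerate (point-mass) posteriors it
    avoids arbitrarily including a few probability-one probes whose cost
    happens to fit under the running mean.
    """
    n = local_prob.size
    order = np.argsort(local_prob, kind="stable")
    sorted_p = local_prob[order]
    running = np.cumsum(sorted_p) / np.arange(1, n + 1)
    boundary = np.empty(n, dtype=bool)
    boundary[:-1] = sorted_p[:-1] < sorted_p[1:]
    boundary[-1] = True
    keep = np.nonzero((running <= alpha) & boundary)[0]
    mask = np.zeros(n, dtype=bool)
    if keep.size:
        mask[order[: keep[-1] + 1]] = True
    return mask


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")


def fdr_track(
    track: EffectTrack, delta: float, alpha: float = 0.05, side: Optional[str] = None
) -> FdrTrack:
    """Probe-wise Bayesian FDR for a (linear-combination) effect track.

    ``side='above'`` detects F(t) > delta (overexpression): the local
    false-call probability is P(F(t) < delta | Y). ``side='below'`` detects
    F(t) < -delta: local probability P(F(t) > -delta | Y). ``two_sided``
    takes the per-probe minimum of the two directions.
    """
    _check_alpha(alpha)
    if side is None:
        side = track.side
    if delta < 0:
        raise ConfigurationError(f"threshold delta must be >= 0, got {delta}")
    if side not in ("above", "below", "two_sided"):
        raise ConfigurationError(f"unknown side {side!r}")
    mean, sd = track.mean, track.sd

    def _local(which: str) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            if which == "above":
                p = norm.cdf((delta - mean) / sd)
                point = (mean < delta).astype(float)
            else:
                p = 1.0 - norm.cdf((-delta - mean) / sd)
                point = (mean > -delta).astype(float)
        return np.where(sd > 0, p, point)

    if side == "two_sided":
        local = np.minimum(_local("above"), _local("below"))
    else:
        local = _local(side)
    return FdrTrack(local, _bayes_fdr_mask(local, alpha), alpha, label=f"{track.label} [{side}]")


def circadian_fdr(
    track: EffectTrack,
    delta: float,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: Optional[int] = None,
) -> FdrTrack:
    """Monte-Carlo Bayesian FDR for the circadian amplitude.

    A(t) depends non-linearly on the sine and cosine effect functions, so the
    posterior tail is approximated by simulation: draw from the independent
    component posteriors, form A_sim(t), and take the proportion of draws with
    A_sim(t) < delta as the local false-call probability.
    """
    _check_alpha(alpha)
    if track.mode != "circadian" or track.components is None:
        raise ConfigurationError("circadian_fdr requires a circadian amplitude track")
    if n_sim < 100:
        raise ConfigurationError(f"n_sim must be >= 100, got {n_sim}")
    sin_m, sin_sd, cos_m, cos_sd = track.components
    rng = np.random.default_rng(seed)
    t = sin_m.size
    below = np.zeros(t, dtype=np.int64)
    # simulate in blocks to bound memory at ~n_block x T doubles
    n_block = max(1, min(n_sim, 4_000_000 // max(t, 1)))
    done = 0
    while done < n_sim:
        k = min(n_block, n_sim - done)
        s = rng.normal(sin_m, sin_sd, size=(k, t))
        c = rng.normal(cos_m, cos_sd, size=(k, t))
        below += np.sum(np.hypot(s, c) < delta, axis=0)
        done += k
    local = below / n_sim
    return FdrTrack(
        local,
        _bayes_fdr_mask(local, alpha),
        alpha,
        label=f"{track.label} [amplitude>{delta:g}]",
        n_sim=n_sim,
        seed=seed,
    )
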