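"""Synthetic tiling experiments with known ground truth.

Generates probe-level data under the exact working model of the fit: equally
spaced probes along one chromosome strand, design-driven effect functions
built from a baseline plus localized bumps, and iid Gaussian noise,

    Y = X B + E,   E_i(t) ~ N(0, sigma^2).

Every simulated experiment writes the same TSV/BED formats the ingest path
reads, so it doubles as an end-to-end fixture. An optional AR(1) noise flag
exists for robustness experiments only; the default matches the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .designs import DesignMatrix, DesignSpec, build_design
from .errors import DataError
from .fit import fit_model
from .inference import circadian_fdr, effect_track, fdr_track
from .regions import ProbeAnnotation, call_regions

__all__ = ["EffectRegion", "SimulationSpec", "GroundTruth", "simulate", "benchmark"]


@dataclass(frozen=True)
class EffectRegion:
    """A planted bump: probe interval [start, stop), effect role, amplitude.

    Amplitude semantics by role: ``group_diff`` - the between-group mean
    difference (the +/-1 coding coefficient is amplitude/2); ``amplitude`` -
    the circadian amplitude A, split over sine and cosine by ``phase``
    (radians); any other role - the coefficient of the matching design column
    on its original coding.
    """

    start: int
    stop: int
    role: str
    amplitude: float
    phase: float = 0.0


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic tiling experiment."""

    design: DesignSpec
    T: int = 1024
    probe_spacing_bp: int = 35
    probe_length_bp: int = 25
    effect_regions: Sequence[EffectRegion] = ()
    baseline: float = 6.0
    noise_sd: float = 0.3
    seed: int = 0
    chromosome: str = "chr1"
    strand: str = "+"
    taper_probes: int = 0
    ar1_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise DataError("T must be >= 2")
        if self.noise_sd < 0:
            raise DataError("noise sd must be >= 0")
        for reg in self.effect_regions:
            if not 0 <= reg.start < reg.stop <= self.T:
                raise DataError(
                    f"effect interval [{reg.start}, {reg.stop}) outside [0, {self.T})"
                )


@dataclass
class GroundTruth:
    """True effect-function matrix (original design coding) and regions."""

    B: np.ndarray  # (q, T)
    regions: pd.DataFrame  # role, start, stop, amplitude (probe indices)
    design: DesignMatrix

    def true_mask(self, role: Optional[str] = None) -> np.ndarray:
        mask = np.zeros(self.B.shape[1], dtype=bool)
        for row in self.regions.itertuples():
            if role is None or row.role == role:
                mask[row.start : row.stop] = True
        return mask


def _bump(T: int, start: int, stop: int, taper: int) -> np.ndarray:
    shape = np.zeros(T)
    shape[start:stop] = 1.0
    width = stop - start
    if taper > 0 and 2 * taper <= width:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(taper) + 0.5) / taper))
        shape[start : start + taper] = ramp
        shape[stop - taper : stop] = ramp[::-1]
    return shape


def simulate(spec: SimulationSpec) -> tuple[ExpressionMatrix, ProbeAnnotation, GroundTruth]:
    """Draw one experiment; identical spec (incl. seed) gives identical output."""
    design = build_design(spec.design)
    x_orig = design.original
    q, T = design.q, spec.T
    roles = design.column_roles

    B = np.zeros((q, T))
    B[0, :] = spec.baseline
    rows = []
    for reg in spec.effect_regions:
        shape = _bump(T, reg.start, reg.stop, spec.taper_probes)
        if reg.role == "group_diff" and design.kind == "two_group":
            B[1] += (reg.amplitude / 2.0) * shape
        elif reg.role == "amplitude":
            if "sine" not in roles or "cosine" not in roles:
                raise DataError("role 'amplitude' requires a circadian design")
            B[roles.index("sine")] += reg.amplitude * np.cos(reg.phase) * shape
            B[roles.index("cosine")] += reg.amplitude * np.sin(reg.phase) * shape
        elif reg.role in roles:
            B[roles.index(reg.role)] += reg.amplitude * shape
        else:
            raise DataError(f"effect role {reg.role!r} not among design roles {roles}")
        rows.append(
            {"role": reg.role, "start": reg.start, "stop": reg.stop, "amplitude": reg.amplitude}
        )

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(scale=spec.noise_sd, size=(design.n_arrays, T)) if spec.noise_sd > 0 else 0.0
    if spec.ar1_rho != 0.0 and spec.noise_sd > 0:
        rho = spec.ar1_rho
        colored = np.array(noise, copy=True)
        for t in range(1, T):
            colored[:, t] = rho * colored[:, t - 1] + np.sqrt(1 - rho**2) * noise[:, t]
        noise = colored
    values = x_orig @ B + noise

    expr = ExpressionMatrix(values=values)
    probes = ProbeAnnotation(
        chromosome=spec.chromosome,
        strand=spec.strand,
        starts=np.arange(T, dtype=np.int64) * spec.probe_spacing_bp,
        probe_length=spec.probe_length_bp,
    )
    truth = GroundTruth(
        B=B,
        regions=pd.DataFrame(rows, columns=["role", "start", "stop", "amplitude"]),
        design=design,
    )
    return expr, probes, truth


def _boundary_error_probes(regions, probes: ProbeAnnotation, start: int, stop: int) -> float:
    """Max boundary offset (in probes) of the best-overlapping called region."""
    if len(regions) == 0:
        return float("inf")
    true_lo = probes.starts[start]
    true_hi = probes.starts[stop - 1] + probes.probe_length
    best, best_ov = None, -1
    for row in regions.table.itertuples():
        ov = min(row.end, true_hi) - max(row.start, true_lo)
        if ov > best_ov:
            best, best_ov = row, ov
    if best_ov <= 0:
        return float("inf")
    spacing = probes.median_spacing
    return max(abs(best.start - true_lo), abs(best.end - true_hi)) / spacing


def benchmark(
    spec: SimulationSpec,
    n_replicates: int = 20,
    alpha: float = 0.05,
    delta: float = 0.2,
    mode: str = "compare",
    selector=None,
    smoothing: str = "common",
    min_probes: int = 4,
    max_gap_bp: Optional[int] = None,
    n_sim: int = 1000,
) -> dict[str, pd.DataFrame]:
    """Run the full fit -> inference -> regions pipeline over seeded replicates.

    Per replicate, computes probe-level sensitivity and observed false
    discovery proportion against the planted truth, plus the region boundary
    error for the first planted region. Returns ``{"replicates": ...,
    "summary": ...}`` with mean and sd per metric.
    """
    if n_replicates < 1:
        raise DataError("n_replicates must be >= 1")
    if selector is None and mode == "compare":
        selector = (0, 1)
    records = []
    for rep in range(n_replicates):
        rspec = SimulationSpec(
            **{**spec.__dict__, "seed": spec.seed + rep}
        )
        expr, probes, truth = simulate(rspec)
        fit = fit_model(expr, truth.design, smoothing=smoothing)
        track = effect_track(fit, mode, selector)
        if mode == "circadian":
            fdr = circadian_fdr(track, delta, alpha, n_sim=n_sim, seed=rspec.seed)
            called = fdr.significant
            local = fdr.local_prob
        else:
            up = fdr_track(track, delta, alpha, side="above")
            down = fdr_track(track, delta, alpha, side="below")
            called = up.significant | down.significant
            local = np.minimum(up.local_prob, down.local_prob)
        true_mask = truth.true_mask()
        tp = int(np.sum(called & true_mask))
        fp = int(np.sum(called & ~true_mask))
        n_true = int(true_mask.sum())
        sens = tp / n_true if n_true else float("nan")
        fdp = fp / max(tp + fp, 1)
        rec = {
            "replicate": rep,
            "seed": rspec.seed,
            "sensitivity": sens,
            "fdp": fdp,
            "n_called": tp + fp,
        }
        if len(truth.regions):
            regs = call_regions(
                called,
                probes,
                min_probes=min_probes,
                max_gap_bp=max_gap_bp,
                effect=track.mean,
                local_fdr=local,
            )
            first = truth.regions.iloc[0]
            rec["boundary_error_probes"] = _boundary_error_probes(
                regs, probes, int(first.start), int(first.stop)
            )
            rec["n_regions"] = len(regs)
        records.append(rec)
    reps = pd.DataFrame(records)
    metrics = [c for c in reps.columns if c not in ("replicate", "seed")]
    summary = pd.DataFrame({"mean": reps[metrics].mean(), "sd": reps[metrics].std(ddof=1)})
    return {"replicates": reps, "summary": summary}
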