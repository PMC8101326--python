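"""Synthetic two-class plasma miRNA cohorts with normalization disturbance.

The generator is the package's test bed: it plants class-shifted signal
pairs into a log2 expression matrix, corrupts every sample with its own
additive log-scale offset (the "no reliable normalizer" problem that
ratio features are built to cancel), attaches stage/age/sex structure,
and renders the same cohort into RT-qPCR Ct space.

Generative model, per miRNA i and sample s (all in log2 units)::

    value(i, s) = baseline_i + biology(i, s) + class_shift(i, s)
                  + offset_s + measurement_noise(i, s)

Signal is planted symmetrically: in case samples the up member of a signal
pair rises by delta/2 and the down member falls by delta/2, so the pair
feature carries the full effect delta while each single miRNA carries only
half — stressing the pairing advantage. Early-stage cases get their shift
attenuated. ``offset_s ~ N(0, sample_offset_sd)`` hits all miRNAs of a
sample equally.

Every additive component is quantized to a fixed grid (2^-16 log2 units by
default, emulating the fixed decimal precision of exported chip data).
Because all quantities are then exact binary64 values well inside the
mantissa, per-sample offsets cancel *bit-exactly* in pair features, which
makes the normalizer-free invariance testable as strict equality.

Ct rendering uses the ideal-efficiency model ``Ct = ct_intercept - log2
abundance`` plus Gaussian Ct noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, write_expression_matrix, write_metadata)

__all__ = ["SimConfig", "simulate_cohort", "render_ct", "make_fixtures", "quantize"]


def quantize(x: np.ndarray, quantum: float) -> np.ndarray:
    """Round to integer multiples of ``quantum`` (a power of two → exact)."""
    if quantum <= 0:
        return np.asarray(x, dtype=float)
    return np.round(np.asarray(x, dtype=float) / quantum) * quantum


@dataclass
class SimConfig:
    """All parameters of the synthetic cohort.

    Defaults define the package's standard study conditions: 100 cases vs
    100 controls, 40 miRNAs, two planted pairs of effect 1.5 log2 units
    sharing the down-regulated member (so the planted pairs are the unique
    strongest ratio features and recovery is well-posed), sample offsets of
    SD 1.5 — three times the per-value measurement noise of SD 0.5 — and a
    Ct rendering with 0.25 cycles of technical noise.
    """

    n_case: int = 100
    n_control: int = 100
    n_mirna: int = 40
    baseline_mean_range: tuple[float, float] = (4.0, 14.0)
    baseline_sd: float = 0.5
    signal_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 2, 1.5), (1, 2, 1.5)])
    sample_offset_sd: float = 1.5
    measurement_sd: float = 0.5
    stage_fraction_early: float = 0.3
    early_attenuation: float = 0.6
    age_effect: float = 0.0
    ct_intercept: float = 38.0
    ct_noise_sd: float = 0.25
    seed: int = 0
    quantum: float = 2.0 ** -16

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per class")
        if self.n_mirna < 2:
            raise ValueError("need at least 2 miRNAs")
        for sd in (self.baseline_sd, self.sample_offset_sd, self.measurement_sd,
                   self.ct_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.stage_fraction_early <= 1:
            raise ValueError("stage_fraction_early must be in [0, 1]")
        if not 0 < self.early_attenuation <= 1:
            raise ValueError("early_attenuation must be in (0, 1]")
        for up, down, delta in self.signal_pairs:
            if up == down:
                raise ValueError("signal pair indices must be distinct")
            if not (0 <= up < self.n_mirna and 0 <= down < self.n_mirna):
                raise ValueError("signal pair index out of range")
            if delta <= 0:
                raise ValueError("signal pair delta must be positive")

    def mirna_name(self, i: int) -> str:
        return f"miR-{i:03d}"

    def planted_pairs(self) -> list[tuple[str, str]]:
        """Canonically oriented (lexicographic) planted pair names."""
        return [tuple(sorted((self.mirna_name(u), self.mirna_name(d))))
                for u, d, _ in self.signal_pairs]


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(config: SimConfig):
    """Generate one cohort.

    Returns ``(ExpressionMatrix, metadata DataFrame, truth dict)``. The
    truth record carries the planted pair names, per-sample offsets and
    stages for downstream oracle checks. Deterministic given
    ``config.seed``.
    """
    c = config
    (rng_base, rng_bio, rng_shift_stage, rng_off, rng_eps,
     rng_age, rng_sex, _rng_ct) = _streams(c.seed, 8)

    m, n = c.n_mirna, c.n_case + c.n_control
    q = c.quantum
    mirnas = [c.mirna_name(i) for i in range(m)]
    sample_ids = ([f"case_{i:04d}" for i in range(c.n_case)]
                  + [f"ctrl_{i:04d}" for i in range(c.n_control)])
    y = np.array([1] * c.n_case + [0] * c.n_control)

    lo, hi = c.baseline_mean_range
    baseline = rng_base.uniform(lo, hi, size=m)
    biology = rng_bio.normal(0.0, c.baseline_sd, size=(m, n))
    eps = rng_eps.normal(0.0, c.measurement_sd, size=(m, n))

    stage = np.array([None] * n, dtype=object)
    is_early = np.zeros(n, dtype=bool)
    draws = rng_shift_stage.random(n)
    for s in range(n):
        if y[s] == 1:
            is_early[s] = draws[s] < c.stage_fraction_early
            stage[s] = "early" if is_early[s] else "advanced"

    shift = np.zeros((m, n))
    atten = np.where(is_early, c.early_attenuation, 1.0)
    for up, down, delta in c.signal_pairs:
        shift[up, y == 1] += (delta / 2.0) * atten[y == 1]
        shift[down, y == 1] -= (delta / 2.0) * atten[y == 1]

    offsets = rng_off.normal(0.0, c.sample_offset_sd, size=n)
    # quantize the biological part and the offsets separately so that the
    # final sum is exact in binary64 and offsets cancel bit-exactly in ratios
    body = quantize(baseline[:, None] + biology + shift + eps, q)
    offsets_q = quantize(offsets, q)
    values = body + offsets_q[None, :]

    frame = pd.DataFrame(values, index=mirnas, columns=sample_ids)
    expr = ExpressionMatrix(frame, scale_tag="log2")

    age = np.round(rng_age.normal(60.0, 10.0, size=n) + c.age_effect * y, 1)
    age = np.clip(age, 18.0, 95.0)
    sex = np.where(rng_sex.random(n) < 0.5, "female", "male")
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "label": np.where(y == 1, "case", "control"),
        "age": age,
        "sex": sex,
        "stage": stage,
    })

    truth = {
        "planted_pairs": [list(p) for p in config.planted_pairs()],
        "signal_pairs_indexed": [list(t) for t in c.signal_pairs],
        "sample_offsets": offsets_q.tolist(),
        "stages": [None if s is None else str(s) for s in stage],
        "seed": c.seed,
    }
    return expr, meta, truth


def render_ct(expr: ExpressionMatrix, config: SimConfig) -> ExpressionMatrix:
    """Ct-space rendering: ``Ct = ct_intercept - log2value + noise``.

    Uses its own random stream derived from ``config.seed``, so rendering
    is deterministic and independent of cohort generation order.
    """
    if expr.scale_tag != "log2":
        raise ValueError("render_ct expects a log2-scale matrix")
    rng_ct = _streams(config.seed, 8)[7]
    q = config.quantum
    eta = quantize(rng_ct.normal(0.0, config.ct_noise_sd, size=expr.shape), q)
    ct = (config.ct_intercept - expr.values.to_numpy()) + eta
    if (ct <= 0).any():
        raise ValueError("ct_intercept too small: rendered non-positive Ct values")
    frame = pd.DataFrame(ct, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(frame, scale_tag="ct")


def make_fixtures(directory: str | Path, config: SimConfig | None = None) -> dict[str, Path]:
    """Write expression/Ct/metadata TSVs plus a truth JSON into ``directory``."""
    config = config or SimConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr, meta, truth = simulate_cohort(config)
    ct = render_ct(expr, config)
    paths = {
        "expression": directory / "expression.tsv",
        "ct": directory / "ct.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    write_expression_matrix(expr, paths["expression"])
    write_expression_matrix(ct, paths["ct"])
    write_metadata(meta, paths["metadata"])
    truth_doc = dict(truth)
    truth_doc["config"] = asdict(config)
    paths["truth"].write_text(json.dumps(truth_doc, indent=2) + "\n")
    return paths
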