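"""Endpoint-fluorescence genotype calling.

A KASP plate read gives every sample a pair of channel intensities; the
three genotype clusters lie along angles near 0 degrees (recipient-allele
fluorophore, x axis), 45 degrees (heterozygote) and 90 degrees (donor-allele
fluorophore). Calling is one-dimensional k-means on the signal angle with
fixed seeds at 0/45/90, a minimum-intensity floor, and a no-call guard band
around cluster boundaries. Calls are therefore invariant to uniform scaling
of both channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import HET, HOM_ALT, HOM_REF, MISSING, ValidationError

CANONICAL_ANGLES = {HOM_REF: 0.0, HET: 45.0, HOM_ALT: 90.0}


@dataclass(frozen=True)
class CallerParams:
    min_intensity: float = 0.1   # radial floor below which a well is no-call
    guard_band_deg: float = 10.0  # no-call margin around cluster boundaries
    max_iter: int = 50


@dataclass
class FluorescencePlate:
    """Per-sample two-channel endpoint intensities.

    ``signal_x`` is the recipient-allele fluorophore channel, ``signal_y``
    the donor-allele channel; ``control`` flags non-sample wells.
    """

    data: pd.DataFrame  # columns: signal_x, signal_y, control(bool)

    def __post_init__(self):
        required = {"signal_x", "signal_y"}
        if not required <= set(self.data.columns):
            raise ValidationError(f"plate frame needs columns {sorted(required)}")
        if "control" not in self.data.columns:
            self.data = self.data.assign(control=False)
        if (self.data[["signal_x", "signal_y"]] < 0).any().any():
            raise ValidationError("negative intensities on plate")
        if (~self.data["control"]).sum() < 3:
            raise ValidationError("need at least 3 non-control samples")


def _kmeans_1d(theta: np.ndarray, seeds: np.ndarray, max_iter: int) -> np.ndarray:
    centers = seeds.astype(float).copy()
    for _ in range(max_iter):
        assign = np.argmin(np.abs(theta[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for k in range(len(centers)):
            if (assign == k).any():
                new[k] = theta[assign == k].mean()
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers)
    if not np.array_equal(order, np.arange(len(centers))):
        centers = centers[order]
    return centers


def call_genotypes(plate: FluorescencePlate, params: CallerParams = CallerParams()) -> pd.Series:
    """Genotype calls for a plate column: 0/1/2 with -1 for no-calls.

    Samples under the intensity floor are missing; after angular k-means,
    samples within the guard band of a cluster boundary are demoted to
    missing. If fewer than three clusters are occupied, het-adjacent calls
    are demoted to missing.
    """
    df = plate.data
    x = df["signal_x"].to_numpy(float)
    y = df["signal_y"].to_numpy(float)
    radius = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x))
    usable = (~df["control"].to_numpy(bool)) & (radius >= params.min_intensity)

    calls = np.full(len(df), MISSING, dtype=np.int8)
    if usable.sum() >= 3:
        centers = _kmeans_1d(theta[usable], np.array([0.0, 45.0, 90.0]), params.max_iter)
        boundaries = (centers[:-1] + centers[1:]) / 2.0
        assign = np.digitize(theta, boundaries)  # 0, 1, 2 by angle band
        near_boundary = np.zeros(len(df), dtype=bool)
        for b in boundaries:
            near_boundary |= np.abs(theta - b) < params.guard_band_deg
        occupied = len(np.unique(assign[usable & ~near_boundary]))
        calls[usable] = assign[usable]
        calls[usable & near_boundary] = MISSING
        if occupied < 3:
            # degenerate plate: het calls are unreliable, demote them
            calls[(calls == HET)] = MISSING
    return pd.Series(calls, index=df.index, name="call")


def render_fluorescence(
    truth: pd.Series | np.ndarray,
    noise: float,
    rng,
    base_radius: float = 1.0,
) -> FluorescencePlate:
    """Synthetic plate read from genotype truth.

    Truth classes map to the canonical 0/45/90-degree angles with Gaussian
    angular noise (scaled to ``noise`` x 45 degrees) and radial noise;
    missing truth renders as sub-threshold signal near the origin.
    """
    if not 0 <= noise < 0.5:
        raise ValidationError(f"noise must be in [0, 0.5), got {noise}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = np.asarray(truth)
    index = truth.index if isinstance(truth, pd.Series) else pd.RangeIndex(len(t))
    angles = np.array([CANONICAL_ANGLES.get(int(g), np.nan) for g in t])
    jitter = rng.normal(0.0, noise * 45.0, size=len(t))
    theta = np.clip(angles + jitter, 0.0, 90.0)
    radius = np.maximum(base_radius + rng.normal(0.0, noise * base_radius, size=len(t)), 1e-6)
    missing = np.isnan(angles)
    theta[missing] = 45.0
    radius[missing] = 1e-3  # below any sensible intensity floor
    rad = np.radians(theta)
    df = pd.DataFrame(
        {
            "signal_x": radius * np.cos(rad),
            "signal_y": radius * np.sin(rad),
            "control": False,
        },
        index=index,
    )
    plate = FluorescencePlate(df)
    plate.data.attrs["class_counts"] = pd.Series(t).value_counts().to_dict()
    return plate


def call_matrix(
    truth_frame: pd.DataFrame, noise: float, rng, params: CallerParams = CallerParams()
) -> pd.DataFrame:
    """Render-and-call every marker column of a truth frame."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = {}
    for marker in truth_frame.columns:
        plate = render_fluorescence(truth_frame[marker], noise, rng)
        out[marker] = call_genotypes(plate, params)
    return pd.DataFrame(out, index=truth_frame.index).astype(np.int8)
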