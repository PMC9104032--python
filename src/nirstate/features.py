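"""Gaussian-basis GLM feature extraction.

Each epoch trace is modelled as a linear combination of unit-peak
Gaussian "bells" of σ = 1 s spaced 1 s apart across the window (centers
at 0.5, 1.5, ..., 7.5 s for an 8-s epoch).  The ordinary-least-squares
fitted heights of the bells summarise the hemodynamic waveform shape and
are the classifier features, concatenated over long channels and both
chromophores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet

__all__ = [
    "GaussianBasis",
    "GlmFit",
    "FeatureMatrix",
    "build_basis",
    "glm_fit",
    "extract_features",
]

CHROMOPHORES = ("hbo", "hbr")


@dataclass(frozen=True)
class GaussianBasis:
    sigma: float
    spacing: float
    centers: np.ndarray  # s, within the epoch
    design: np.ndarray  # (samples, n_basis)
    sampling_rate: float

    @property
    def n_basis(self) -> int:
        return self.design.shape[1]


@dataclass
class GlmFit:
    heights: np.ndarray  # β per basis function, µM
    reconstruction: np.ndarray
    residual_norm: float


@dataclass
class FeatureMatrix:
    """Rows = epochs, columns = (channel × chromophore × basis) heights."""

    values: np.ndarray
    labels: list[str]
    column_names: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("label count does not match row count")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column-name count does not match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


def build_basis(
    duration: float,
    rate: float,
    sigma: float = 1.0,
    spacing: float = 1.0,
    first_center: float | None = None,
) -> GaussianBasis:
    """Shifted unit-peak Gaussians covering [0, duration).

    Centers default to spacing/2, 3·spacing/2, ... — symmetric in the
    window with no center outside the data; 8 functions for the default
    8-s epoch.  Column k is exp(−(t − c_k)² / (2σ²)) on the epoch's
    sample grid t = 0, 1/rate, 2/rate, ...
    """
    if duration <= 0 or spacing <= 0 or sigma <= 0:
        raise ValueError("duration, spacing and sigma must be positive")
    if spacing > duration:
        raise ValueError("basis spacing exceeds the epoch duration")
    c0 = spacing / 2.0 if first_center is None else first_center
    centers = np.arange(c0, duration, spacing)
    n = int(np.rint(duration * rate))
    t = np.arange(n) / rate
    design = np.exp(-((t[:, None] - centers[None, :]) ** 2) / (2.0 * sigma**2))
    return GaussianBasis(
        sigma=sigma, spacing=spacing, centers=centers, design=design,
        sampling_rate=rate,
    )


def glm_fit(trace: np.ndarray, basis: GaussianBasis) -> GlmFit:
    """OLS fit of one trace to the basis; heights are the β estimates."""
    trace = np.asarray(trace, dtype=float)
    x = basis.design
    if trace.shape[0] != x.shape[0]:
        raise ValueError(
            f"trace length {trace.shape[0]} != design rows {x.shape[0]}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns for the error message
        _, r = np.linalg.qr(x)
        bad = [int(i) for i in np.where(np.abs(np.diag(r)) < 1e-10)[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    heights, *_ = np.linalg.lstsq(x, trace, rcond=None)
    recon = x @ heights
    return GlmFit(
        heights=heights,
        reconstruction=recon,
        residual_norm=float(np.linalg.norm(trace - recon)),
    )


def extract_features(epochs: EpochSet, basis: GaussianBasis, chromophore: str = "both") -> FeatureMatrix:
    """Bell heights per (channel × chromophore), concatenated per epoch.

    ``chromophore`` selects ``"hbo"``, ``"hbr"`` or ``"both"`` (default:
    one matrix holding both, channels-major column order).
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch set")
    if chromophore not in CHROMOPHORES + ("both",):
        raise ValueError("chromophore must be 'hbo', 'hbr' or 'both'")
    chroms = CHROMOPHORES if chromophore == "both" else (chromophore,)
    chrom_idx = {"hbo": 0, "hbr": 1}
    names = [
        f"{cid}:{ch}:bell{k}"
        for cid in epochs.channel_ids
        for ch in chroms
        for k in range(basis.n_basis)
    ]
    rows = []
    for ep in epochs.epochs:
        if ep.data.shape[0] != basis.design.shape[0]:
            raise ValueError(
                f"epoch has {ep.data.shape[0]} samples but basis expects "
                f"{basis.design.shape[0]}"
            )
        feats = [
            glm_fit(ep.data[:, j, chrom_idx[ch]], basis).heights
            for j in range(len(epochs.channel_ids))
            for ch in chroms
        ]
        rows.append(np.concatenate(feats))
    return FeatureMatrix(
        values=np.vstack(rows), labels=list(epochs.labels), column_names=names
    )
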