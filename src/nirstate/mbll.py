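"""Modified Beer-Lambert law: raw intensity -> optical density -> ΔHbO/ΔHbR.

For a continuous-wave instrument the attenuation change at wavelength λ
relative to a baseline interval is the optical density

    OD_λ(t) = -log10( I_λ(t) / <I_λ>_baseline ),

and the modified Beer-Lambert law relates it linearly to chromophore
concentration changes through the source-detector distance d and the
differential pathlength factor (DPF):

    OD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR) · d · DPF_λ .

With two wavelengths this is a 2x2 linear system per channel and sample,
solved exactly for (ΔHbO, ΔHbR).  Internally ε is in cm⁻¹·M⁻¹, d in cm
and concentrations in mol/L; the public containers carry µM and mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .montage import MontageSpec

__all__ = [
    "OpticsConstants",
    "OpticalRecording",
    "OpticalDensitySeries",
    "HemoSeries",
    "default_constants",
    "load_constants",
    "intensity_to_od",
    "od_to_hemoglobin",
]

MOLAR_PER_MICROMOLAR = 1e-6
MM_PER_CM = 10.0


@dataclass(frozen=True)
class OpticsConstants:
    """Extinction coefficients and differential pathlength factors.

    ``extinction[wavelength] = (eps_hbo, eps_hbr)`` in cm⁻¹·M⁻¹;
    ``dpf[wavelength]`` is dimensionless (default 6.0 at both wavelengths,
    a common adult-head value).
    """

    extinction: dict[float, tuple[float, float]]
    dpf: dict[float, float]

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 extinction matrix [[ε_HbO,λ1, ε_HbR,λ1], [ε_HbO,λ2, ε_HbR,λ2]]."""
        try:
            rows = [self.extinction[wl] for wl in wavelengths]
        except KeyError as exc:
            raise KeyError(
                f"no extinction entry for wavelength {exc.args[0]} nm"
            ) from None
        e = np.asarray(rows, dtype=float)
        if abs(np.linalg.det(e)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        return e

    def condition_number(self, wavelengths: tuple[float, float]) -> float:
        return float(np.linalg.cond(self.matrix(wavelengths)))


def load_constants(path, dpf: dict[float, float] | None = None) -> OpticsConstants:
    """Read an extinction table (wavelength_nm, eps_hbo, eps_hbr TSV)."""
    ext: dict[float, tuple[float, float]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        wl, eo, er = ln.split("\t")
        ext[float(wl)] = (float(eo), float(er))
    if not ext:
        raise ValueError(f"no extinction rows found in {path}")
    if dpf is None:
        dpf = {wl: 6.0 for wl in ext}
    return OpticsConstants(extinction=ext, dpf=dpf)


def default_constants() -> OpticsConstants:
    """Bundled Gratzer/Prahl tabulation for 760 and 850 nm, DPF 6.0."""
    with resources.as_file(
        resources.files("nirstate.data").joinpath("extinction.tsv")
    ) as p:
        return load_constants(p)


@dataclass
class OpticalRecording:
    """Raw two-wavelength intensity series with events and montage reference.

    ``intensity`` has shape (n_samples, n_channels, n_wavelengths), in
    arbitrary units, strictly positive.  ``events`` is a list of
    (onset_s, duration_s, label) tuples.
    """

    time: np.ndarray
    intensity: np.ndarray
    channel_ids: tuple[str, ...]
    wavelengths_nm: tuple[float, float]
    sampling_rate: float
    events: list[tuple[float, float, str]] = field(default_factory=list)
    montage: MontageSpec | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (samples, channels, wavelengths)")
        if self.intensity.shape[0] != self.time.shape[0]:
            raise ValueError("time and intensity sample counts differ")
        if self.intensity.shape[1] != len(self.channel_ids):
            raise ValueError("channel axis does not match channel_ids")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time base must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("non-uniform sampling detected")
        if np.any(self.intensity <= 0):
            s, c, w = np.argwhere(self.intensity <= 0)[0]
            raise ValueError(
                f"non-positive intensity at sample {s}, channel "
                f"{self.channel_ids[c]}, wavelength {self.wavelengths_nm[w]} nm"
            )
        dur = self.time[-1] if len(self.time) else 0.0
        for onset, _d, label in self.events:
            if onset < 0 or onset > dur:
                raise ValueError(f"event {label!r} at {onset} s outside record")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]


@dataclass
class OpticalDensitySeries:
    """Dimensionless attenuation change relative to the baseline window."""

    time: np.ndarray
    od: np.ndarray  # (samples, channels, wavelengths)
    channel_ids: tuple[str, ...]
    wavelengths_nm: tuple[float, float]
    sampling_rate: float
    baseline_window: tuple[float, float]
    events: list[tuple[float, float, str]] = field(default_factory=list)
    montage: MontageSpec | None = None


@dataclass
class HemoSeries:
    """Per-channel ΔHbO/ΔHbR in µM, relative to the optical-density baseline."""

    time: np.ndarray
    hbo: np.ndarray  # (samples, channels), µM
    hbr: np.ndarray
    channel_ids: tuple[str, ...]
    sampling_rate: float
    events: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo/hbr shape mismatch")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("non-finite concentration values")


def intensity_to_od(
    rec: OpticalRecording, baseline_window: tuple[float, float] = (0.0, 5.0)
) -> OpticalDensitySeries:
    """OD(t) = -log10(I(t) / mean(I over the baseline window)).

    The baseline is the arithmetic mean intensity over ``baseline_window``
    (default: the first 5 s of the record), per channel and wavelength.
    """
    lo, hi = baseline_window
    mask = (rec.time >= lo) & (rec.time < hi)
    if not np.any(mask):
        raise ValueError(f"baseline window {baseline_window} contains no samples")
    base = rec.intensity[mask].mean(axis=0)  # (channels, wavelengths)
    od = -np.log10(rec.intensity / base)
    return OpticalDensitySeries(
        time=rec.time,
        od=od,
        channel_ids=rec.channel_ids,
        wavelengths_nm=rec.wavelengths_nm,
        sampling_rate=rec.sampling_rate,
        baseline_window=baseline_window,
        events=list(rec.events),
        montage=rec.montage,
    )


def od_to_hemoglobin(
    od: OpticalDensitySeries,
    montage: MontageSpec | None = None,
    constants: OpticsConstants | None = None,
    *,
    include_short: bool = False,
) -> HemoSeries:
    """Invert the 2x2 modified Beer-Lambert system per channel and sample.

    Short-separation channels are converted identically but excluded from
    the output by default; they sample scalp, not cortex, and contribute
    no features downstream.
    """
    montage = montage if montage is not None else od.montage
    if montage is None:
        raise ValueError("a montage is required to resolve channel distances")
    constants = constants if constants is not None else default_constants()
    e = constants.matrix(od.wavelengths_nm)  # cm^-1 M^-1
    dpf = np.array([constants.dpf[wl] for wl in od.wavelengths_nm])

    keep = [
        (i, montage.channel(cid))
        for i, cid in enumerate(od.channel_ids)
        if include_short or montage.channel(cid).kind == "long"
    ]
    n = od.od.shape[0]
    hbo = np.empty((n, len(keep)))
    hbr = np.empty((n, len(keep)))
    for j, (i, ch) in enumerate(keep):
        pathlen = (ch.distance_mm / MM_PER_CM) * dpf  # cm, per wavelength
        a = e * pathlen[:, None]  # OD = a @ [dHbO, dHbR] (mol/L)
        conc = np.linalg.solve(a, od.od[:, i, :].T)  # (2, samples), mol/L
        hbo[:, j] = conc[0] / MOLAR_PER_MICROMOLAR
        hbr[:, j] = conc[1] / MOLAR_PER_MICROMOLAR
    return HemoSeries(
        time=od.time,
        hbo=hbo,
        hbr=hbr,
        channel_ids=tuple(ch.id for _, ch in keep),
        sampling_rate=od.sampling_rate,
        events=list(od.events),
    )
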