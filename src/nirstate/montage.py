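"""Probe geometry: channels, source-detector distances, regions of interest.

The default montage models a prefrontal CW-fNIRS probe: ten long
(~30 mm) channels built from 9 sources and 4 detectors covering the
middle frontal gyrus (MFG) and bilateral dorsolateral prefrontal cortex
(DLPFC), plus two 10 mm short-separation channels at F3 and F4 whose
light samples mainly scalp hemodynamics.  Downstream computation uses
only each channel's source-detector distance and ROI label, so optode
scalp coordinates are not modelled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

__all__ = [
    "ROI_LABELS",
    "Channel",
    "MontageSpec",
    "default_montage",
    "channels_by_roi",
    "dumps_montage",
    "loads_montage",
    "save_montage",
    "load_montage",
]

#: Recognised region-of-interest labels.  SHORT marks short-separation channels.
ROI_LABELS = ("MFG", "L-DLPFC", "R-DLPFC", "SHORT")

LONG_DISTANCE_MM = 30.0
SHORT_DISTANCE_MM = 10.0
#: Half-width of the band around 30 mm accepted for a "long" channel.
LONG_DISTANCE_TOL_MM = 5.0


@dataclass(frozen=True)
class Channel:
    """One source-detector pair.

    Parameters
    ----------
    id : str
        Stable channel identifier, e.g. ``"S1-D1"``.
    source_id, detector_id : str
        Optode identifiers; must resolve within the parent montage.
    distance_mm : float
        Source-detector separation in millimetres.
    roi : str
        One of :data:`ROI_LABELS`.
    kind : str
        ``"long"`` (cortical) or ``"short"`` (scalp, 10 mm).
    """

    id: str
    source_id: str
    detector_id: str
    distance_mm: float
    roi: str
    kind: str
    #: accepted deviation from the nominal 30 mm for long channels
    distance_tol_mm: float = LONG_DISTANCE_TOL_MM

    def __post_init__(self) -> None:
        if self.roi not in ROI_LABELS:
            raise ValueError(
                f"unknown ROI {self.roi!r}; valid labels: {', '.join(ROI_LABELS)}"
            )
        if self.kind not in ("long", "short"):
            raise ValueError(f"channel kind must be 'long' or 'short', got {self.kind!r}")
        if self.kind == "short":
            if self.distance_mm != SHORT_DISTANCE_MM:
                raise ValueError(
                    f"short channel {self.id} must have distance "
                    f"{SHORT_DISTANCE_MM} mm, got {self.distance_mm}"
                )
            if self.roi != "SHORT":
                raise ValueError(f"short channel {self.id} must carry roi=SHORT")
        else:
            if abs(self.distance_mm - LONG_DISTANCE_MM) > self.distance_tol_mm:
                raise ValueError(
                    f"long channel {self.id}: distance {self.distance_mm} mm outside "
                    f"{LONG_DISTANCE_MM}±{self.distance_tol_mm} mm"
                )
            if self.roi == "SHORT":
                raise ValueError(f"long channel {self.id} cannot carry roi=SHORT")


@dataclass(frozen=True)
class MontageSpec:
    """An ordered set of channels plus the optode bookkeeping.

    ``n_sources``/``n_detectors`` count the long-channel probe; dedicated
    short-channel emitters (if any) are extra and recorded implicitly by
    the channels themselves.
    """

    channels: tuple[Channel, ...]
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    n_sources: int = 9
    n_detectors: int = 4
    name: str = "default"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel ids in montage")

    @property
    def long_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.kind == "long")

    @property
    def short_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.kind == "short")

    def channel(self, channel_id: str) -> Channel:
        for c in self.channels:
            if c.id == channel_id:
                return c
        raise KeyError(channel_id)


def default_montage(
    *,
    n_left: int = 4,
    n_right: int = 4,
    n_mfg: int = 2,
    short_dedicated_sources: bool = True,
) -> MontageSpec:
    """Build the study montage: 10 long + 2 short channels, (760, 850) nm.

    The long-channel ROI split defaults to 4 L-DLPFC / 4 R-DLPFC / 2 MFG
    over 9 sources and 4 detectors.  Short channels sit at F3/F4; by
    default they use dedicated emitters (S10, S11) so the stated 9/4
    optode counts refer to the long probe only.
    """
    if n_left + n_right + n_mfg != 10:
        raise ValueError("default montage requires 10 long channels in total")
    pairings = [
        ("S1", "D1"), ("S2", "D1"), ("S3", "D1"), ("S4", "D1"),  # left
        ("S4", "D2"), ("S5", "D2"),                              # midline
        ("S6", "D3"), ("S7", "D3"), ("S8", "D4"), ("S9", "D4"),  # right
    ]
    rois = ["L-DLPFC"] * n_left + ["MFG"] * n_mfg + ["R-DLPFC"] * n_right
    channels = [
        Channel(
            id=f"{s}-{d}", source_id=s, detector_id=d,
            distance_mm=LONG_DISTANCE_MM, roi=roi, kind="long",
        )
        for (s, d), roi in zip(pairings, rois)
    ]
    short_sources = ("S10", "S11") if short_dedicated_sources else ("S1", "S6")
    for src, det, pos in zip(short_sources, ("D1", "D3"), ("F3", "F4")):
        channels.append(
            Channel(
                id=f"SS-{pos}", source_id=src, detector_id=det,
                distance_mm=SHORT_DISTANCE_MM, roi="SHORT", kind="short",
            )
        )
    return MontageSpec(channels=tuple(channels))


def channels_by_roi(montage: MontageSpec, roi: str) -> tuple[Channel, ...]:
    """Channels tagged with `roi`, in montage order."""
    if roi not in ROI_LABELS:
        raise ValueError(
            f"unknown ROI {roi!r}; valid labels: {', '.join(ROI_LABELS)}"
        )
    return tuple(c for c in montage.channels if c.roi == roi)


# -- plain-text serialization -------------------------------------------------

_HEADER_KEYS = ("name", "wavelengths_nm", "n_sources", "n_detectors")


def dumps_montage(montage: MontageSpec) -> str:
    buf = io.StringIO()
    buf.write(f"# nirstate montage v1\n")
    buf.write(f"name\t{montage.name}\n")
    buf.write(
        "wavelengths_nm\t%g,%g\n" % tuple(montage.wavelengths_nm)
    )
    buf.write(f"n_sources\t{montage.n_sources}\n")
    buf.write(f"n_detectors\t{montage.n_detectors}\n")
    buf.write("id\tsource_id\tdetector_id\tdistance_mm\troi\tkind\n")
    for c in montage.channels:
        buf.write(
            f"{c.id}\t{c.source_id}\t{c.detector_id}\t{c.distance_mm:g}\t{c.roi}\t{c.kind}\n"
        )
    return buf.getvalue()


def loads_montage(text: str) -> MontageSpec:
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    meta: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].split("\t")[0] in _HEADER_KEYS:
        key, val = lines[i].split("\t", 1)
        meta[key] = val
        i += 1
    header = lines[i].split("\t")
    if header[:3] != ["id", "source_id", "detector_id"]:
        raise ValueError("malformed montage file: missing channel table header")
    channels = []
    for ln in lines[i + 1 :]:
        cid, src, det, dist, roi, kind = ln.split("\t")
        channels.append(
            Channel(id=cid, source_id=src, detector_id=det,
                    distance_mm=float(dist), roi=roi, kind=kind)
        )
    wl = tuple(float(x) for x in meta["wavelengths_nm"].split(","))
    return MontageSpec(
        channels=tuple(channels),
        wavelengths_nm=wl,  # type: ignore[arg-type]
        n_sources=int(meta["n_sources"]),
        n_detectors=int(meta["n_detectors"]),
        name=meta.get("name", "unnamed"),
    )


def save_montage(montage: MontageSpec, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(dumps_montage(montage))


def load_montage(path) -> MontageSpec:
    with open(path, encoding="utf-8") as fh:
        return loads_montage(fh.read())
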