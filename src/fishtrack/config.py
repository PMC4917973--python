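"""Pipeline configuration: parameter profiles and a key=value config reader.

Two profiles ship with the thresholds used for the original zebrafish test
groups (D1: 20 fish, D2: 40 fish, recorded at 2048 x 2040 px where a fish
spans roughly 150-300 px), plus a SYNTH profile matched to the synthetic
renderer's 60-px fish, with thresholds derived from its geometry by the same
rules (T_w midway between the rendered head- and tail-endpoint widths, T_u
below half the body boundary length).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .segmentation import SegmentationParams
from .centerline import CenterlineParams
from .head_detect import HeadDetectParams
from .head_direction import DirectionParams
from .tracking import TrackingParams


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # segmentation
    t_g: float = 75.0
    n_background_frames: int = 100
    min_blob_area: int = 30
    median_kernel: int = 3
    # centerline
    t_u: float = 70.0
    # head endpoint
    t_l: float = 9.0
    t_w: float = 16.0
    # head direction
    scales: tuple = (2.0, 3.0, 4.0, 6.0, 8.0)
    anisotropy_min: float = 1.2
    # tracking
    omega: float = 0.5
    pc_max: float = 60.0
    dc_max: float = 180.0
    t_o: float = 300.0
    n_fish: int = 20
    # io
    polarity: str = "dark"       # fish darker than background ("dark") or lighter
    match_radius: float = 30.0   # for scoring; half the nominal fish length

    def __post_init__(self) -> None:
        if self.polarity not in ("dark", "light"):
            raise ConfigError("polarity must be 'dark' or 'light'")
        # delegate range checks to the per-module param types
        self.segmentation_params()
        self.centerline_params()
        self.head_detect_params()
        self.direction_params()
        self.tracking_params()

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(t_g=self.t_g, n_background_frames=self.n_background_frames,
                                  min_blob_area=self.min_blob_area, median_kernel=self.median_kernel)

    def centerline_params(self) -> CenterlineParams:
        return CenterlineParams(t_u=self.t_u)

    def head_detect_params(self) -> HeadDetectParams:
        return HeadDetectParams(t_l=self.t_l, t_w=self.t_w)

    def direction_params(self) -> DirectionParams:
        return DirectionParams(scales=tuple(self.scales), anisotropy_min=self.anisotropy_min)

    def tracking_params(self) -> TrackingParams:
        return TrackingParams(omega=self.omega, pc_max=self.pc_max, dc_max=self.dc_max,
                              t_o=self.t_o, n_fish=self.n_fish)


PROFILES: dict[str, dict] = {
    # zebrafish groups, thresholds as published for each test set
    "D1": dict(t_g=75.0, t_u=70.0, t_l=9.0, t_w=16.0,
               omega=0.5, pc_max=60.0, dc_max=180.0, t_o=300.0, n_fish=20),
    "D2": dict(t_g=40.0, t_u=40.0, t_l=7.0, t_w=9.0,
               omega=0.4, pc_max=80.0, dc_max=180.0, t_o=350.0, n_fish=40),
    # matched to the synthetic renderer (60-px fish, head/tail half-widths 8/2)
    "SYNTH": dict(t_g=60.0, t_u=30.0, t_l=9.0, t_w=11.0,
                  omega=0.5, pc_max=60.0, dc_max=180.0, t_o=150.0, n_fish=10,
                  n_background_frames=200, match_radius=30.0),
}

_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}
_INT_KEYS = {"n_background_frames", "min_blob_area", "median_kernel", "n_fish"}
_STR_KEYS = {"polarity"}


def profile_config(name: str, **overrides) -> PipelineConfig:
    if name not in PROFILES:
        raise ConfigError(f"unknown profile {name!r}; available: {sorted(PROFILES)}")
    kw = dict(PROFILES[name])
    kw.update(overrides)
    return PipelineConfig(**kw)


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key == "scales":
        try:
            return tuple(float(v) for v in raw.replace(",", " ").split())
        except ValueError:
            raise ConfigError(f"bad value for 'scales': {raw!r}")
    if key in _STR_KEYS:
        return raw
    try:
        return int(raw) if key in _INT_KEYS else float(raw)
    except ValueError:
        raise ConfigError(f"bad value for {key!r}: {raw!r}")


def load_config(path: str | Path, profile: str | None = None) -> PipelineConfig:
    """Read a ``key = value`` config file on top of a profile's defaults.

    Lines starting with '#' are comments.  A ``profile`` key inside the file
    selects the base profile (a ``profile`` argument wins).  Unknown keys and
    out-of-range values raise :class:`ConfigError` naming the key.
    """
    path = Path(path)
    pairs: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{ln}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        pairs[key] = raw
    base = profile or pairs.pop("profile", "D1")
    if profile is not None:
        pairs.pop("profile", None)
    kw = dict(PROFILES.get(base) or _raise_profile(base))
    for key, raw in pairs.items():
        if key not in _FIELD_TYPES:
            raise ConfigError(f"unknown config key {key!r}")
        kw[key] = _parse_value(key, raw)
    try:
        return PipelineConfig(**kw)
    except ValueError as e:
        raise ConfigError(str(e)) from e


def _raise_profile(name: str):
    raise ConfigError(f"unknown profile {name!r}; available: {sorted(PROFILES)}")
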