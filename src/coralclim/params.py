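"""Analysis constants for the bleaching-projection pipeline.

Every fixed number used by the method lives here: the climatology and
baseline windows, the projection horizon, the degree-heating-week (DHW)
threshold that defines severe bleaching stress, the degree-heating-month
to DHW conversion, the run length that defines the onset of *annual*
severe bleaching (ASB), and the cutoff years that split reef pixels into
relative climate losers / average / winners.

Defaults are the standard values of the downscaled-projection method;
all of them can be overridden through a YAML config for sensitivity runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisParams", "default_params", "load_params", "save_params"]


@dataclass(frozen=True)
class AnalysisParams:
    """Fixed parameters of the downscaling / ASB-onset analysis.

    Year windows are inclusive ``(first, last)`` tuples.

    Attributes
    ----------
    clim_window
        Years of the observed climatology (default 1982-2008).
    baseline_window
        Years whose downscaled mean is pinned to the climatology mean
        (default 2006-2011).
    projection_window
        Years covered by the projections (default 2006-2099).
    dhw_threshold
        Stress level in DHW that must be exceeded (strictly) for a year
        to count as a severe-bleaching year (default 8.0).
    dhm_to_dhw_factor
        Weeks per month: degree heating months x 4.35 = DHW.
    run_length
        Number of consecutive exceedance years defining ASB onset (10).
    window_months
        Length of the sliding accumulation window in months (3).
    loser_cutoff
        Pixels with onset strictly before this year are relative climate
        losers (default 2034).
    winner_cutoff
        Pixels with onset strictly after this year are relative climate
        winners (default 2053); onsets in [loser_cutoff, winner_cutoff]
        are "average".
    """

    clim_window: tuple[int, int] = (1982, 2008)
    baseline_window: tuple[int, int] = (2006, 2011)
    projection_window: tuple[int, int] = (2006, 2099)
    dhw_threshold: float = 8.0
    dhm_to_dhw_factor: float = 4.35
    run_length: int = 10
    window_months: int = 3
    loser_cutoff: int = 2034
    winner_cutoff: int = 2053

    def __post_init__(self) -> None:
        for name in ("clim_window", "baseline_window", "projection_window"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has first year {lo} > last year {hi}")
        if self.dhw_threshold <= 0:
            raise ValueError("dhw_threshold must be positive")
        if self.dhm_to_dhw_factor <= 0:
            raise ValueError("dhm_to_dhw_factor must be positive")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.window_months < 1:
            raise ValueError("window_months must be >= 1")
        # the observation era may overlap the first projection years
        # (1982-2008 vs 2006-2099) but must begin before them
        if self.clim_window[0] >= self.projection_window[0]:
            raise ValueError("climatology window must start before the projection window")
        b0, b1 = self.baseline_window
        p0, p1 = self.projection_window
        if not (p0 <= b0 and b1 <= p1):
            raise ValueError("baseline_window must lie inside projection_window")
        if self.loser_cutoff >= self.winner_cutoff:
            raise ValueError("loser_cutoff must be earlier than winner_cutoff")

    @property
    def last_onset_year(self) -> int:
        """Latest year an ASB run can start and still fit the projection."""
        return self.projection_window[1] - self.run_length + 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("clim_window", "baseline_window", "projection_window"):
            d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        kwargs = dict(d)
        for name in ("clim_window", "baseline_window", "projection_window"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    def replace(self, **changes) -> "AnalysisParams":
        return dataclasses.replace(self, **changes)


def default_params() -> AnalysisParams:
    """The standard parameter set of the analysis."""
    return AnalysisParams()


def save_params(params: AnalysisParams, path: str | Path) -> None:
    """Write parameters to a YAML file (round-trips with :func:`load_params`)."""
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))


def load_params(path: str | Path) -> AnalysisParams:
    """Read parameters from a YAML file; missing keys take defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisParams.from_dict(data)
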