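"""Synthetic chromatograms and gel lanes with the statistical structure
the caller assumes.

Each expressed subunit contributes a Gaussian peak centered at its
reference mean RT plus optional jitter drawn from N(0, (scale * sd)^2).
The overexpressed Bx7OE variant gets double amplitude.  Optional LMW
clutter is confined to 42-55 min, outside the HMW window.
"""

from __future__ import annotations

import numpy as np

from .caller import CultivarProfile
from .chromatogram import Chromatogram
from .config import SimConfig
from .errors import ConfigurationError
from .gel import GelLane, MobilityTable
from .reference import ReferenceTable

#: clutter band kept clear of the 42-min window edge so peak tails cannot leak in
_CLUTTER_RANGE = (42.6, 54.4)
_CLUTTER_COUNT = (8, 16)
_CLUTTER_AMPLITUDE = (20.0, 120.0)


def _gaussian(t: np.ndarray, center: float, sigma: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_chromatogram(
    profile: CultivarProfile, table: ReferenceTable, cfg: SimConfig | None = None
) -> Chromatogram:
    """Simulate one trace for a cultivar; deterministic under a fixed seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.time_range
    n = int(round((hi - lo) / cfg.grid_step)) + 1
    t = np.linspace(lo, hi, n)
    y = np.zeros_like(t)

    for sub in sorted(profile.subunits()):  # fixed draw order for reproducibility
        if sub not in table.entries:
            raise ConfigurationError(f"{profile.name}: subunit {sub} missing from reference table")
        entry = table.entry(sub)
        center = entry.mean_rt
        if cfg.rt_jitter_scale > 0:
            center += cfg.rt_jitter_scale * entry.sd_rt * rng.standard_normal()
        amplitude = cfg.amplitude * (cfg.oe_factor if sub.label == "7OE" else 1.0)
        y += _gaussian(t, center, cfg.peak_sigma, amplitude)

    if cfg.lmw_clutter:
        count = int(rng.integers(_CLUTTER_COUNT[0], _CLUTTER_COUNT[1] + 1))
        centers = rng.uniform(*_CLUTTER_RANGE, size=count)
        amps = rng.uniform(*_CLUTTER_AMPLITUDE, size=count)
        for c, a in zip(centers, amps):
            y += _gaussian(t, c, cfg.peak_sigma, a)

    if cfg.baseline_noise_sd > 0:
        y += rng.normal(0.0, cfg.baseline_noise_sd, size=t.shape)

    return Chromatogram(time=t, absorbance=y, sample_id=profile.name)


def simulate_gel(profile: CultivarProfile, mobility: MobilityTable) -> GelLane:
    """One band per expressed subunit; co-migrating subunits merge."""
    ranks = sorted({mobility.rank_of(sub) for sub in profile.subunits()})
    return GelLane(sample_id=profile.name, bands=ranks)
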