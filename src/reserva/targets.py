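"""Range-size-dependent conservation targets.

Each feature (species or ecosystem) is assigned the fraction of its extent
that must end up inside the selected reserve network.  Restricted-range
features get the highest fraction, widespread ones the lowest, with linear
interpolation in between; a scenario scale factor s shrinks the whole
scheme (s = 0.4 turns the base 90–10% gradient into 36–4%)."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .landscape import FeatureAmountMatrix

__all__ = ["TargetScheme", "target_fraction", "build_target_table", "achievement_report"]

#: relative slack when deciding whether a target amount is met, absorbing
#: float accumulation across PU sums
MET_RTOL = 1e-9


@dataclass(frozen=True)
class TargetScheme:
    """Endpoints and range thresholds of the target interpolation.

    ``t_max`` applies below the small-range threshold, ``t_min`` above the
    widespread threshold (km²); thresholds differ for species and
    ecosystems.  ``scale`` multiplies every fraction.
    """

    t_max: float = 0.90
    t_min: float = 0.10
    species_thresholds: tuple[float, float] = (10_000.0, 75_000.0)
    ecosystem_thresholds: tuple[float, float] = (100.0, 10_000.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max <= 1):
            raise ValueError("need 0 < t_min < t_max <= 1")
        for lo, hi in (self.species_thresholds, self.ecosystem_thresholds):
            if not lo < hi:
                raise ValueError("small-range threshold must be below widespread threshold")
        if not (0 < self.scale <= 1):
            raise ValueError("scale must be in (0, 1]")

    def halved(self) -> "TargetScheme":
        """The same scheme with every target fraction cut in half."""
        return replace(self, scale=self.scale / 2)

    def thresholds_for(self, kind: str) -> tuple[float, float]:
        if kind == "species":
            return self.species_thresholds
        if kind == "ecosystem":
            return self.ecosystem_thresholds
        raise ValueError(f"unknown feature kind {kind!r}")


def target_fraction(range_km2: float, kind: str, scheme: TargetScheme) -> float:
    """Target fraction for a feature of the given extent.

    Piecewise linear and continuous: s·t_max below A_small, s·t_min above
    A_large, linear in between (the value at the thresholds equals the
    endpoints, so the boundary convention is unambiguous).
    """
    if range_km2 <= 0:
        raise ValueError("feature range must be positive")
    a_small, a_large = scheme.thresholds_for(kind)
    s = scheme.scale
    if range_km2 < a_small:
        return s * scheme.t_max
    if range_km2 > a_large:
        return s * scheme.t_min
    frac = scheme.t_max + (scheme.t_min - scheme.t_max) * (range_km2 - a_small) / (a_large - a_small)
    return s * frac


def build_target_table(features: FeatureAmountMatrix, scheme: TargetScheme) -> pd.DataFrame:
    """One target row per feature; achievement starts from the amount already
    inside locked-in (protected-zone) planning units."""
    fracs = np.array([
        target_fraction(ext, kind, scheme)
        for ext, kind in zip(features.total_extent, features.kind)
    ])
    target = fracs * features.total_extent
    achieved = features.protected_amount.astype(float)
    return pd.DataFrame({
        "feature_id": features.feature_ids,
        "kind": features.kind,
        "extent_km2": features.total_extent,
        "fraction": fracs,
        "target_km2": target,
        "protected_km2": achieved,
        "met": achieved >= target * (1 - MET_RTOL),
    })


def achievement_report(
    achieved_km2: np.ndarray,
    targets: pd.DataFrame,
) -> dict:
    """Share of features whose achieved amount meets the target.

    ``achieved_km2`` is the per-feature km² inside the evaluated PU set
    (selected plus locked-in), aligned with the rows of ``targets``.
    """
    achieved = np.asarray(achieved_km2, dtype=float)
    if achieved.shape[0] != len(targets):
        raise ValueError("achieved vector misaligned with target table")
    met = achieved >= targets["target_km2"].to_numpy() * (1 - MET_RTOL)
    kind = targets["kind"].to_numpy()

    def share(sel: np.ndarray) -> float:
        return 100.0 * met[sel].mean() if sel.any() else 100.0

    return {
        "pct_species_met": share(kind == "species"),
        "pct_ecosystems_met": share(kind == "ecosystem"),
        "pct_all_met": 100.0 * met.mean() if len(met) else 100.0,
        "n_met": int(met.sum()),
        "n_features": int(len(met)),
        "met": met,
    }
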