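"""Förster-distance geometry of an RNA three-way junction.

Converts apparent FRET efficiencies to inter-fluorophore distances via
the Förster relation R = R0 * ((1-E)/E)^(1/6), models each helical arm
as an ideal A-form duplex (contour length = base pairs x rise), and
ranks coaxial-stacking hypotheses for the junction: under a hypothesis
that two arms stack, those arms are collinear and the end-to-end label
distance across them is the sum of their contour lengths, while the
third arm pivots in the junction plane with a free angle fit to the
remaining measurements.

The Förster radius is taken as given (60 Å for the Cy3/Cy5 pair used
here); no kappa-squared orientation correction or linker offsets are
applied, so distances are label-position estimates on the same footing
as apparent FRET. The stacked-pair -> junction-family labelling
(Lescoute-Westhof A/B/C) is configuration data, not a hard-coded rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "A_FORM_RISE",
    "DEFAULT_FAMILY_MAP",
    "ForsterParams",
    "HelixArm",
    "StackingHypothesis",
    "fret_to_distance",
    "distance_to_fret",
    "helix_contour_length",
    "rank_stacking_models",
    "estimate_distances",
]

#: Axial rise per base pair of an ideal A-form RNA helix, in Å.
A_FORM_RISE = 2.8

#: Conventional stacked-pair -> family labels for this junction: stems
#: I/II stacked is family A; stem I with the U4 5' stem-loop is the
#: previously proposed family B arrangement; the remaining pair is C.
DEFAULT_FAMILY_MAP: Mapping[frozenset, str] = {
    frozenset({"stem I", "stem II"}): "A",
    frozenset({"stem I", "5' stem-loop"}): "B",
    frozenset({"stem II", "5' stem-loop"}): "C",
}


@dataclass(frozen=True)
class ForsterParams:
    """Förster radius of the dye pair, in Å."""

    r0: float = 60.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("R0 must be positive")


@dataclass(frozen=True)
class HelixArm:
    """A junction arm modelled as an ideal A-form duplex."""

    name: str
    length_bp: int
    rise_per_bp: float = A_FORM_RISE

    def __post_init__(self) -> None:
        if self.length_bp < 0:
            raise ValueError("length_bp must be non-negative")
        if not 2.0 < self.rise_per_bp < 3.5:
            raise ValueError("rise_per_bp must lie in (2.0, 3.5) Å")


@dataclass(frozen=True)
class StackingHypothesis:
    stacked_pair: tuple[str, str]
    family: Optional[str]
    predicted_label_distance: float
    residual: float
    bend_angle_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stacked_pair[0] == self.stacked_pair[1]:
            raise ValueError("stacked arms must be distinct")
        if self.predicted_label_distance < 0:
            raise ValueError("predicted distance must be non-negative")


def fret_to_distance(efficiency: float, params: Optional[ForsterParams] = None) -> float:
    """Inter-fluorophore distance (Å) from apparent FRET efficiency.

    R = R0 * ((1 - E) / E)^(1/6). E must lie strictly inside (0, 1).
    """
    params = params or ForsterParams()
    e = float(efficiency)
    if not 0.0 < e < 1.0:
        raise ValueError("efficiency must lie strictly in (0, 1)")
    return params.r0 * ((1.0 - e) / e) ** (1.0 / 6.0)


def distance_to_fret(distance: float, params: Optional[ForsterParams] = None) -> float:
    """FRET efficiency at a given inter-fluorophore distance (Å).

    E = 1 / (1 + (R / R0)^6); strictly decreasing in R.
    """
    params = params or ForsterParams()
    r = float(distance)
    if r <= 0:
        raise ValueError("distance must be positive")
    return 1.0 / (1.0 + (r / params.r0) ** 6)


def helix_contour_length(arm: HelixArm) -> float:
    """Contour length of an arm in Å (base pairs x axial rise)."""
    return arm.length_bp * arm.rise_per_bp


def _pair_key(a: str, b: str) -> frozenset:
    return frozenset({a, b})


def rank_stacking_models(
    arms: Sequence[HelixArm],
    measurements: Sequence[tuple[tuple[str, str], float]],
    family_map: Optional[Mapping[frozenset, str]] = None,
    angle_step_deg: float = 0.05,
    min_bend_deg: float = 20.0,
) -> list[StackingHypothesis]:
    """Rank coaxial-stacking hypotheses against measured label distances.

    ``measurements`` is a list of ((arm_name, arm_name), distance_Å)
    pairs giving end-to-end distances between arm tips. For each
    candidate stacked pair the two stacked arms are collinear (predicted
    tip-to-tip distance = sum of contour lengths) and the third arm's
    in-plane angle is fit on a grid to minimize the summed absolute
    residual over all measurements. The free arm must be genuinely bent:
    its angle to either stacked arm is kept at least ``min_bend_deg``
    away from collinear, otherwise every hypothesis could mimic coaxial
    stacking of a measured pair and the hypotheses would not be
    distinguishable. Hypotheses are returned sorted by residual (ties
    broken by arm names), so the ordering is independent of measurement
    and arm input order.
    """
    if len(arms) != 3:
        raise ValueError("exactly three arms are required")
    if len(measurements) == 0:
        raise ValueError("at least one measurement is required")
    names = [a.name for a in arms]
    if len(set(names)) != 3:
        raise ValueError("arm names must be distinct")
    lengths = {a.name: helix_contour_length(a) for a in arms}
    for (na, nb), _ in measurements:
        if na not in lengths or nb not in lengths:
            raise ValueError(f"measurement references unknown arm: {na!r}/{nb!r}")
    family_map = DEFAULT_FAMILY_MAP if family_map is None else family_map

    theta = np.deg2rad(
        np.arange(min_bend_deg, 180.0 - min_bend_deg + angle_step_deg, angle_step_deg)
    )
    hypotheses = []
    for x_name, y_name in [
        (names[i], names[j]) for i in range(3) for j in range(i + 1, 3)
    ]:
        x_name, y_name = sorted((x_name, y_name))
        z_name = next(n for n in names if n not in (x_name, y_name))
        lx, ly, lz = lengths[x_name], lengths[y_name], lengths[z_name]
        predicted = lx + ly

        # residual as a function of the third arm's angle to arm X
        # (angle to arm Y is pi - theta since X and Y are collinear)
        res = np.zeros_like(theta)
        for (na, nb), d in measurements:
            key = _pair_key(na, nb)
            if key == _pair_key(x_name, y_name):
                res += abs(predicted - d)
            elif key == _pair_key(x_name, z_name):
                pred = np.sqrt(lx**2 + lz**2 - 2 * lx * lz * np.cos(theta))
                res += np.abs(pred - d)
            elif key == _pair_key(y_name, z_name):
                pred = np.sqrt(ly**2 + lz**2 + 2 * ly * lz * np.cos(theta))
                res += np.abs(pred - d)
        i_best = int(np.argmin(res))
        uses_angle = any(
            _pair_key(na, nb) != _pair_key(x_name, y_name)
            for (na, nb), _ in measurements
        )
        hypotheses.append(
            StackingHypothesis(
                stacked_pair=(x_name, y_name),
                family=family_map.get(_pair_key(x_name, y_name)),
                predicted_label_distance=predicted,
                residual=float(res[i_best]),
                bend_angle_deg=float(np.rad2deg(theta[i_best])) if uses_angle else None,
            )
        )
    return sorted(hypotheses, key=lambda h: (h.residual, h.stacked_pair))


def estimate_distances(
    model,
    params: Optional[ForsterParams] = None,
    mean_errors: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Distances for each mixture-component mean with propagated error.

    Standard errors of the component mean FRET values are pushed through
    the Förster relation to first order: sd(R) = |dR/dE| * sd(E).
    Component means outside (0, 1) are flagged and their distance left
    as NaN.
    """
    params = params or ForsterParams()
    means = np.asarray(model.means, dtype=float)
    if mean_errors is None:
        mean_errors = np.zeros_like(means)
    mean_errors = np.asarray(mean_errors, dtype=float)
    rows = []
    for i, (e, se) in enumerate(zip(means, mean_errors)):
        if not 0.0 < e < 1.0:
            rows.append(
                dict(component=i, mean_fret=e, se_fret=se, distance_A=np.nan,
                     se_distance_A=np.nan, flagged=True)
            )
            continue
        r = fret_to_distance(e, params)
        # dR/dE = -R0/6 * ((1-E)/E)^(-5/6) / E^2
        u = (1.0 - e) / e
        drde = -params.r0 / 6.0 * u ** (-5.0 / 6.0) / e**2
        rows.append(
            dict(component=i, mean_fret=e, se_fret=se, distance_A=r,
                 se_distance_A=abs(drde) * se, flagged=False)
        )
    return pd.DataFrame(rows)
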