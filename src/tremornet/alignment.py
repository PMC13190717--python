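"""Per-patient network-alignment scores against a template network.

Each patient's On-Off metabolic change map is scored against the template
over the template's nonzero voxels, either by Spearman rank correlation
(the primary metric) or by the sum of voxel-wise products (the robustness
metric). Scores are z-scored across the cohort before entering outcome
regressions.

Because the template of interest is published left-lateralized while PET
change maps are bilateral, two reconciliation strategies are provided:
mirror the template into a bilateral map, or average each PET map's
hemispheres to the left before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, StandardizationError, SupportError
from .volumes import BrainMap, mirror

_METRICS = ("spearman", "product_sum")


@dataclass
class AlignmentScores:
    ids: list[str]
    raw: np.ndarray
    z: np.ndarray
    metric: str
    support_size: int
    support: str = "nonzero_template"
    note: str = "product_sum is an unnormalized sum over the support"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "raw": self.raw,
                "z": self.z,
                "metric": self.metric,
                "support_size": self.support_size,
            }
        )


def alignment_score(
    delta: BrainMap,
    template: BrainMap,
    metric: str = "spearman",
    min_support: int = 10,
) -> float:
    """Similarity of one change map to the template over nonzero voxels.

    ``spearman``: rank correlation (average ranks for ties).
    ``product_sum``: sum of delta * template over the support (not
    normalized by support size).
    """
    if metric not in _METRICS:
        raise ConfigError(f"metric must be one of {_METRICS}")
    delta.require_same_grid(template)
    support = delta.mask & template.mask & (template.data != 0)
    n_sup = int(support.sum())
    if n_sup < min_support:
        raise SupportError(
            f"template support has {n_sup} voxels (< {min_support})"
        )
    d = delta.data[support]
    t = template.data[support]
    if metric == "spearman":
        if np.ptp(d) == 0 or np.ptp(t) == 0:
            raise SupportError("constant values on the template support")
        rho = stats.spearmanr(d, t).statistic
        return float(rho)
    return float(np.sum(d * t))


def cohort_alignment(
    deltas: list[BrainMap],
    template: BrainMap,
    metric: str = "spearman",
    ids: list[str] | None = None,
) -> AlignmentScores:
    """Raw + cohort-z-scored alignment for every patient's change map.

    z uses the sample (n-1) standard deviation; raw and z orderings are
    identical by construction.
    """
    if len(deltas) < 3:
        raise ConfigError("need at least 3 patients to z-score alignment")
    raw = np.array([alignment_score(d, template, metric) for d in deltas])
    sd = raw.std(ddof=1)
    if sd == 0:
        raise StandardizationError("zero cohort standard deviation of alignment scores")
    z = (raw - raw.mean()) / sd
    support = deltas[0].mask & template.mask & (template.data != 0)
    if ids is None:
        ids = [f"sub-{i + 1:02d}" for i in range(len(deltas))]
    return AlignmentScores(
        ids=list(ids), raw=raw, z=z, metric=metric, support_size=int(support.sum())
    )


def prepare_template(
    template_left: BrainMap, strategy: str = "mirror_template_bilateral"
) -> tuple[BrainMap, str | None]:
    """Reconcile a left-lateralized template with bilateral PET maps.

    Returns ``(template, pet_transform)`` where ``pet_transform`` is
    ``None`` (score change maps as-is) or ``"average_to_left"`` (each
    change map must pass through :func:`tremornet.volumes.mirror` with
    that mode before scoring).
    """
    xcoords = template_left.grid.axis_coords(0)
    has_left = np.any(template_left.mask[xcoords < 0])
    if not has_left:
        raise ConfigError("template has no left-hemisphere voxels")
    if strategy == "mirror_template_bilateral":
        return mirror(template_left, "left_to_right_bilateral"), None
    if strategy == "average_pet_to_left":
        return template_left, "average_to_left"
    raise ConfigError(f"unknown template strategy {strategy!r}")


def apply_pet_transform(delta: BrainMap, pet_transform: str | None) -> BrainMap:
    """Apply the directive emitted by :func:`prepare_template` to a map."""
    if pet_transform is None:
        return delta
    return mirror(delta, pet_transform)
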