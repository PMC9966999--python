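"""Structure-activity landscape: SAS maps, SALI and activity cliffs.

Every unordered compound pair is placed on a structure-activity similarity
(SAS) map: pairwise Tanimoto fingerprint similarity against absolute pIC50
difference. Two thresholds partition the map into four quadrants:

* ``smooth``        — similar structures, similar activity (classic SAR);
* ``activity_cliff``— similar structures, large activity gap;
* ``scaffold_hop``  — dissimilar structures, similar activity;
* ``nondescript``   — dissimilar structures, large activity gap.

SALI (structure-activity landscape index) quantifies a pair's cliff
character: |delta pIC50| / (1 - similarity); identical fingerprints with an
activity gap score infinity. AC generators are compounds that recur across
many activity-cliff pairs; the consensus generator set is the intersection
across fingerprint schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .curation import CompoundRecord
from .descriptors import Fingerprint
from .errors import ConfigurationError

log = logging.getLogger(__name__)

DEFAULT_SIM_THRESHOLD = 0.5
DEFAULT_ACT_THRESHOLD = 2.0

QUADRANTS = ("smooth", "activity_cliff", "nondescript", "scaffold_hop")


@dataclass(frozen=True)
class SASPoint:
    id_a: str
    id_b: str
    similarity: float
    activity_diff: float
    sali: float  # math.inf marks the identical-structure, nonzero-gap case
    quadrant: str


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity; generalized (sum-min / sum-max) for counts.

    For 0/1 vectors this reduces to |A & B| / |A | B|. Two all-zero
    fingerprints compare as 0 with a warning (undefined overlap).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ConfigurationError(f"fingerprint widths differ: {a.size} vs {b.size}")
    num = float(np.minimum(a, b).sum())
    denom = float(np.maximum(a, b).sum())
    if denom == 0:
        log.warning("two all-zero fingerprints: similarity defined as 0")
        return 0.0
    return num / denom


def pairwise_similarity(
    fingerprints: Sequence[Fingerprint],
) -> Iterator[tuple[int, int, float]]:
    """Stream the upper triangle of the pairwise Tanimoto matrix.

    Yields (i, j, similarity) for i < j; n(n-1)/2 values in total.
    """
    if len(fingerprints) < 2:
        raise ConfigurationError("need at least two fingerprints")
    widths = {fp.length for fp in fingerprints}
    if len(widths) > 1:
        raise ConfigurationError(f"mixed fingerprint widths: {sorted(widths)}")
    mats = [fp.bits for fp in fingerprints]
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            yield i, j, tanimoto(mats[i], mats[j])


def sali(activity_diff: float, similarity: float) -> float:
    """SALI = activity difference / (1 - similarity).

    similarity 1 with a nonzero gap -> inf; with zero gap -> 0 by convention.
    """
    if not 0 <= similarity <= 1:
        raise ConfigurationError(f"similarity must be in [0,1], got {similarity}")
    if activity_diff < 0:
        raise ConfigurationError("activity_diff must be non-negative")
    if similarity == 1.0:
        return math.inf if activity_diff > 0 else 0.0
    return activity_diff / (1.0 - similarity)


def classify_quadrant(
    similarity: float,
    activity_diff: float,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    act_threshold: float = DEFAULT_ACT_THRESHOLD,
) -> str:
    if similarity >= sim_threshold:
        return "activity_cliff" if activity_diff >= act_threshold else "smooth"
    return "nondescript" if activity_diff >= act_threshold else "scaffold_hop"


def sas_map(
    records: Sequence[CompoundRecord],
    fingerprints: Mapping[str, Fingerprint],
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    act_threshold: float = DEFAULT_ACT_THRESHOLD,
) -> list[SASPoint]:
    """Build the SAS map over all unordered pairs of one dataset.

    Records align to fingerprints by compound id; id_a < id_b in every
    emitted point. Fewer than two records yield an empty map with a warning.
    """
    if len(records) < 2:
        log.warning("fewer than two records: empty SAS map")
        return []
    missing = [r.compound_id for r in records if r.compound_id not in fingerprints]
    if missing:
        raise ConfigurationError(f"records without fingerprints: {missing[:5]}")
    fps = [fingerprints[r.compound_id] for r in records]
    points = []
    for i, j, sim in pairwise_similarity(fps):
        ra, rb = records[i], records[j]
        if rb.compound_id < ra.compound_id:
            ra, rb = rb, ra
        diff = abs(records[i].pic50 - records[j].pic50)
        points.append(
            SASPoint(
                id_a=ra.compound_id,
                id_b=rb.compound_id,
                similarity=sim,
                activity_diff=diff,
                sali=sali(diff, sim),
                quadrant=classify_quadrant(sim, diff, sim_threshold, act_threshold),
            )
        )
    return points


@dataclass(frozen=True)
class ACReport:
    ac_pairs: tuple[SASPoint, ...]
    generators: tuple[tuple[str, int], ...]  # (compound_id, pair count), ranked
    min_count: int


def ac_generators(points: Sequence[SASPoint], min_count: int = 2) -> ACReport:
    """Rank compounds by activity-cliff pair membership.

    Keeps compounds appearing in at least ``min_count`` AC-quadrant pairs,
    ranked by count descending then id.
    """
    ac_pairs = tuple(p for p in points if p.quadrant == "activity_cliff")
    counts: dict[str, int] = {}
    for p in ac_pairs:
        counts[p.id_a] = counts.get(p.id_a, 0) + 1
        counts[p.id_b] = counts.get(p.id_b, 0) + 1
    ranked = tuple(
        (cid, c)
        for cid, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if c >= min_count
    )
    return ACReport(ac_pairs=ac_pairs, generators=ranked, min_count=min_count)


def consensus_generators(reports: Mapping[str, ACReport]) -> tuple[str, ...]:
    """Generators present under every fingerprint scheme analyzed."""
    sets = [set(cid for cid, _ in rep.generators) for rep in reports.values()]
    if not sets:
        return ()
    common = set.intersection(*sets)
    return tuple(sorted(common))


def sas_frame(points: Sequence[SASPoint]):
    """SAS map as a DataFrame; infinite SALI serializes as the string 'inf'."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "similarity": p.similarity,
                "activity_diff": p.activity_diff,
                "sali": "inf" if math.isinf(p.sali) else p.sali,
                "quadrant": p.quadrant,
            }
            for p in points
        ]
    )
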