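"""Response-consistency and rating-reliability statistics.

Covers the behavioural summaries of the two experiments: the repetition
agreement distribution of the triplet task (the basis of the noise
ceiling), consistency of responses under left/right match swapping, and
inter-rater reliability of attribute ratings via the intraclass
correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .triplet_design import Triplet, experimental_trials

RATING_COLUMNS = ["rater_id", "item_id", "attribute", "value"]


@dataclass
class RatingTable:
    """Ratings of every item on every attribute by every rater, on a 0-100
    visual-analog scale.  The instrument forces all sliders, so missing
    cells are an ingestion error."""

    raters: list[str]
    items: list[int]
    attributes: list[str]
    values: np.ndarray  # (n_raters, n_items, n_attributes)

    def __post_init__(self) -> None:
        expected = (len(self.raters), len(self.items), len(self.attributes))
        if self.values.shape != expected:
            raise DataError(f"rating array shape {self.values.shape} != {expected}")
        if np.isnan(self.values).any():
            raise DataError("rating table has missing cells")
        if self.values.min() < 0 or self.values.max() > 100:
            raise DataError("ratings must lie in [0, 100]")

    def mean_ratings(self) -> pd.DataFrame:
        """Rater-averaged item x attribute means."""
        return pd.DataFrame(
            self.values.mean(axis=0), index=self.items, columns=self.attributes
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ri, rater in enumerate(self.raters):
            for ii, item in enumerate(self.items):
                for ai, attr in enumerate(self.attributes):
                    rows.append((rater, item, attr, self.values[ri, ii, ai]))
        return pd.DataFrame(rows, columns=RATING_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RatingTable":
        missing = [c for c in RATING_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"rating table missing columns: {missing}")
        raters = frame["rater_id"].unique().tolist()
        items = sorted(frame["item_id"].unique().tolist())
        attributes = frame["attribute"].unique().tolist()  # appearance order
        pivot = frame.set_index(["rater_id", "item_id", "attribute"])["value"]
        if pivot.index.has_duplicates:
            raise DataError("duplicate (rater, item, attribute) cells")
        values = np.full((len(raters), len(items), len(attributes)), np.nan)
        r_ix = {r: i for i, r in enumerate(raters)}
        i_ix = {v: i for i, v in enumerate(items)}
        a_ix = {a: i for i, a in enumerate(attributes)}
        for (r, it, a), v in pivot.items():
            values[r_ix[r], i_ix[it], a_ix[a]] = v
        return cls(raters=raters, items=items, attributes=attributes, values=values)


@dataclass
class AgreementDistribution:
    """Split of triplets by how consistently their repetitions were
    answered: all-same, three-of-four majority, or an even split."""

    n_triplets: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_triplets:
            raise DataError("agreement counts do not sum to the triplet count")

    def mean_agreement(self, reps: int = 4) -> float:
        """Average per-triplet agreement: unanimous triplets score 1,
        3-of-4 majorities 0.75, even splits 0.5."""
        u = self.counts.get("unanimous", 0)
        m = self.counts.get("majority3", 0)
        s = self.counts.get("split2", 0)
        return (u * 1.0 + m * 0.75 + s * 0.5) / self.n_triplets


def _chosen_items(trials: pd.DataFrame) -> pd.Series:
    bad = ~trials["response"].isin(["left", "right"])
    if bad.any():
        raise DataError(
            f"trials without a left/right response at rows {list(trials.index[bad][:5])}"
        )
    return trials["match_left"].where(trials["response"] == "left", trials["match_right"])


def agreement_distribution(trials: pd.DataFrame, reps: int = 4) -> AgreementDistribution:
    """Classify each triplet by the split of its repeated responses.

    Responses are compared as chosen *items* (sides are recoded), so
    swapped repetitions group with their originals.  Every triplet must
    have exactly ``reps`` non-catch responses.
    """
    exp = experimental_trials(trials)
    chosen = _chosen_items(exp)
    keys = [
        Triplet.make(int(t), int(l), int(r))
        for t, l, r in zip(exp["target"], exp["match_left"], exp["match_right"])
    ]
    groups: dict[Triplet, list[int]] = {}
    for key, c in zip(keys, chosen):
        groups.setdefault(key, []).append(int(c))
    uneven = [k for k, v in groups.items() if len(v) != reps]
    if uneven:
        raise DataError(f"triplets with repetition count != {reps}: {uneven[:5]}")
    counts = {"unanimous": 0, "majority3": 0, "split2": 0}
    for key, choices in groups.items():
        majority = max(np.bincount(choices))
        if majority == reps:
            counts["unanimous"] += 1
        elif majority * 2 == reps:
            counts["split2"] += 1
        else:
            counts["majority3"] += 1
    return AgreementDistribution(n_triplets=len(groups), counts=counts)


def noise_ceiling_from_distribution(dist: AgreementDistribution, reps: int = 4) -> float:
    """Noise ceiling as the mean repetition agreement (pure function of the
    agreement counts)."""
    return dist.mean_agreement(reps)


def swap_consistency(trials: pd.DataFrame) -> dict:
    """Count trial pairs whose chosen *item* differs between a trial and
    its swapped copy.

    Pairs each unswapped experimental trial with the same triplet's
    swapped presentation from the mirrored participant set (matched by
    position within the set), recoding sides to item identities first.
    """
    exp = experimental_trials(trials)
    chosen = _chosen_items(exp)
    exp = exp.assign(chosen=chosen)
    exp["base_set"] = exp["participant_id"].str.rstrip("s")
    n_differing = 0
    n_pairs = 0
    for _, grp in exp.groupby("base_set"):
        unsw = grp[grp["swapped"] == 0].sort_values("trial_index")
        sw = grp[grp["swapped"] == 1].sort_values("trial_index")
        if len(unsw) == 0 or len(sw) == 0 or len(unsw) != len(sw):
            continue
        n_pairs += len(unsw)
        n_differing += int((unsw["chosen"].to_numpy() != sw["chosen"].to_numpy()).sum())
    if n_pairs == 0:
        raise DataError("no unswapped/swapped trial pairs found")
    return {"n_pairs": n_pairs, "n_differing": n_differing, "fraction": n_differing / n_pairs}


def _icc_anova(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way (items x raters) mean squares: rows=items, cols=raters.
    Returns (MS_items, MS_raters, MS_error)."""
    n, k = values.shape
    grand = values.mean()
    item_means = values.mean(axis=1)
    rater_means = values.mean(axis=0)
    ss_items = k * ((item_means - grand) ** 2).sum()
    ss_raters = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_error = ss_total - ss_items - ss_raters
    ms_items = ss_items / (n - 1)
    ms_raters = ss_raters / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    return ms_items, ms_raters, ms_error


def icc_consistency_avg(table: RatingTable, attribute: str, single: bool = False) -> float:
    """Intraclass correlation of one attribute's ratings, two-way model,
    consistency definition, average-of-k-raters form:

        ICC(C,k) = (MS_items - MS_error) / MS_items

    With ``single=True`` the single-measures form ICC(C,1) is returned
    instead.  Requires at least two raters and two items; zero between-item
    variance leaves reliability undefined.
    """
    if len(table.raters) < 2 or len(table.items) < 2:
        raise ParameterError("ICC requires >= 2 raters and >= 2 items")
    ai = table.attributes.index(attribute)
    values = table.values[:, :, ai].T  # items x raters
    ms_items, _, ms_error = _icc_anova(values)
    if ms_items <= 0:
        raise DataError("zero between-item variance; reliability undefined")
    if single:
        k = values.shape[1]
        return (ms_items - ms_error) / (ms_items + (k - 1) * ms_error)
    return (ms_items - ms_error) / ms_items


def rating_summary(table: RatingTable) -> dict:
    """Descriptive summaries: per-attribute mean and population SD of the
    pooled ratings, and rater-averaged per-item means."""
    flat = table.values.reshape(-1, len(table.attributes))
    return {
        "attribute_means": dict(zip(table.attributes, flat.mean(axis=0))),
        "attribute_sds": dict(zip(table.attributes, flat.std(axis=0))),  # population SD
        "item_means": table.mean_ratings(),
    }
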