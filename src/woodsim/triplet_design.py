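"""Balanced 2AFC match-to-sample triplet designs.

A *triplet* is one trial of the similarity task: a target (test) item shown
with two match items, and the observer picks the match that looks more
similar to the target.  A *design* is a set of unique triplets chosen so
that (i) every item serves as target an almost equal number of times and
(ii) within each target's trials, every other item appears as a match
almost equally often.  Participant sets replicate the design, swap the
left/right match positions on half of the repetitions to control response
bias, and insert catch trials (target duplicated as one match) at fixed
positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, ParameterError

#: 1-indexed positions of the catch trials within the presented sequence.
DEFAULT_CATCH_POSITIONS = (40, 65, 84)

#: Number of flagged practice trials shown before the presented sequence.
DEFAULT_N_PRACTICE = 3

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "target",
    "match_left",
    "match_right",
    "swapped",
    "is_catch",
    "is_practice",
    "response",
]


class Triplet(NamedTuple):
    """One (target, match pair) combination; the match pair is canonical
    (smaller id first) so duplicates are detectable."""

    target: int
    match_a: int
    match_b: int

    @staticmethod
    def make(target: int, a: int, b: int) -> "Triplet":
        if len({target, a, b}) != 3:
            raise DesignError(f"triplet items must be distinct, got {(target, a, b)}")
        return Triplet(target, min(a, b), max(a, b))


@dataclass
class TripletDesign:
    triplets: list[Triplet]
    n_items: int
    coverage: float
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.triplets)) != len(self.triplets):
            raise DesignError("design contains duplicate triplets")

    def __len__(self) -> int:
        return len(self.triplets)

    def target_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_items, dtype=int)
        for t in self.triplets:
            counts[t.target] += 1
        return counts


@dataclass
class ParticipantSet:
    participant_id: str
    trials: pd.DataFrame  # rows in presentation order, TRIAL_COLUMNS schema
    catch_positions: tuple[int, ...]
    swapped_copy_of: str | None = None


# ---------------------------------------------------------------------------
# design sampling
# ---------------------------------------------------------------------------


def _partner_multiset(n_items: int, target: int, n_pairs: int, rng: np.random.Generator) -> list[int]:
    """Partner slots for one target: 2*n_pairs slots spread as evenly as
    possible over the other items (counts differ by at most 1)."""
    partners = [i for i in range(n_items) if i != target]
    n_partners = len(partners)
    base, extra = divmod(2 * n_pairs, n_partners)
    counts = np.full(n_partners, base, dtype=int)
    if extra:
        bumped = rng.choice(n_partners, size=extra, replace=False)
        counts[bumped] += 1
    slots: list[int] = []
    for p, c in zip(partners, counts):
        slots.extend([p] * c)
    return slots


def _pair_slots(slots: list[int], rng: np.random.Generator, max_sweeps: int = 200) -> list[tuple[int, int]]:
    """Pair partner slots into distinct unordered pairs with no self-pairs,
    by random matching followed by seeded edge-swap repair."""
    slots = list(slots)
    for _ in range(max_sweeps):
        order = rng.permutation(len(slots))
        pairs = [
            tuple(sorted((slots[order[2 * k]], slots[order[2 * k + 1]])))
            for k in range(len(slots) // 2)
        ]
        pairs = _repair_pairs(pairs, rng)
        if pairs is not None:
            return pairs
    raise DesignError("could not construct a conflict-free match pairing")


def _conflicts(pairs: list[tuple[int, int]]) -> list[int]:
    seen: dict[tuple[int, int], int] = {}
    bad = []
    for idx, p in enumerate(pairs):
        if p[0] == p[1] or p in seen:
            bad.append(idx)
        else:
            seen[p] = idx
    return bad


def _repair_pairs(
    pairs: list[tuple[int, int]], rng: np.random.Generator, max_iter: int = 2000
) -> list[tuple[int, int]] | None:
    pairs = list(pairs)
    for _ in range(max_iter):
        bad = _conflicts(pairs)
        if not bad:
            return pairs
        i = bad[0]
        j = int(rng.integers(len(pairs)))
        if i == j:
            continue
        a, b = pairs[i]
        c, d = pairs[j]
        pairs[i] = tuple(sorted((a, d)))
        pairs[j] = tuple(sorted((c, b)))
    return None


def sample_design(n_items: int, coverage: float, seed: int) -> TripletDesign:
    """Sample a balanced triplet design covering ``coverage`` of all
    ``n_items * C(n_items - 1, 2)`` (target, match-pair) combinations.

    Targets are assigned ``round(coverage * n * C(n-1, 2))`` triplets as
    evenly as possible (counts differ by at most one across items), and
    within each target the match-pair partners are spread as evenly as
    possible over the remaining items.
    """
    if n_items < 3:
        raise ParameterError(f"n_items must be >= 3, got {n_items}")
    if not 0 < coverage <= 1:
        raise ParameterError(f"coverage must be in (0, 1], got {coverage}")
    n_total_available = n_items * comb(n_items - 1, 2)
    n_triplets = round(coverage * n_total_available)
    if n_triplets > n_total_available:
        raise ParameterError(
            f"requested {n_triplets} triplets but only {n_total_available} unique ones exist"
        )
    if n_triplets == 0:
        raise ParameterError(f"coverage {coverage} yields an empty design")
    rng = np.random.default_rng(seed)

    base, extra = divmod(n_triplets, n_items)
    per_target = np.full(n_items, base, dtype=int)
    if extra:
        bumped = rng.choice(n_items, size=extra, replace=False)
        per_target[bumped] += 1
    if per_target.max() > comb(n_items - 1, 2):
        raise ParameterError("per-target quota exceeds available unique match pairs")

    triplets: list[Triplet] = []
    for target in range(n_items):
        quota = int(per_target[target])
        others = [i for i in range(n_items) if i != target]
        if quota == comb(n_items - 1, 2):  # full coverage: enumerate
            for a, b in itertools.combinations(others, 2):
                triplets.append(Triplet.make(target, a, b))
            continue
        slots = _partner_multiset(n_items, target, quota, rng)
        for a, b in _pair_slots(slots, rng):
            triplets.append(Triplet.make(target, a, b))
    return TripletDesign(triplets=triplets, n_items=n_items, coverage=coverage, seed=seed)


# ---------------------------------------------------------------------------
# participant sets
# ---------------------------------------------------------------------------


def _partition_without_duplicates(
    triplets: Sequence[Triplet], n_copies: int, set_size: int, rng: np.random.Generator
) -> list[list[Triplet]]:
    """Chunk ``n_copies`` shuffled copies of the design into sets of
    ``set_size``, repairing any set that contains the same triplet twice."""
    stream: list[Triplet] = []
    for _ in range(n_copies):
        order = rng.permutation(len(triplets))
        stream.extend(triplets[i] for i in order)
    chunks = [stream[i : i + set_size] for i in range(0, len(stream), set_size)]
    for _ in range(1000):
        fixed = True
        for ci, chunk in enumerate(chunks):
            seen: set[Triplet] = set()
            for pos, trip in enumerate(chunk):
                if trip in seen:
                    cj = int(rng.integers(len(chunks)))
                    pj = int(rng.integers(set_size))
                    chunks[ci][pos], chunks[cj][pj] = chunks[cj][pj], chunks[ci][pos]
                    fixed = False
                    break
                seen.add(trip)
        if fixed:
            return chunks
    raise DesignError("could not partition repetitions into duplicate-free sets")


def _set_frame(
    participant_id: str,
    experimental: list[tuple[Triplet, int, int]],
    practice: list[tuple[Triplet, int, int]],
    catch: list[tuple[int, int, int]],
    catch_positions: Sequence[int],
    swapped: bool,
    swapped_copy_of: str | None,
) -> ParticipantSet:
    """Assemble one participant's presentation-ordered trial frame.

    ``experimental``/``practice`` rows are (triplet, left, right); ``catch``
    rows are (target, left, right).  Catch positions are 1-indexed within
    the presented (non-practice) sequence.
    """
    rows = []
    for trip, left, right in practice:
        rows.append((trip.target, left, right, 0, 1))
    n_presented = len(experimental) + len(catch)
    catch_set = dict(zip(catch_positions, catch))
    exp_iter = iter(experimental)
    for pos in range(1, n_presented + 1):
        if pos in catch_set:
            target, left, right = catch_set[pos]
            rows.append((target, left, right, 1, 0))
        else:
            trip, left, right = next(exp_iter)
            rows.append((trip.target, left, right, 0, 0))
    frame = pd.DataFrame(rows, columns=["target", "match_left", "match_right", "is_catch", "is_practice"])
    if swapped:
        frame[["match_left", "match_right"]] = frame[["match_right", "match_left"]].to_numpy()
    frame.insert(0, "participant_id", participant_id)
    frame.insert(1, "trial_index", np.arange(len(frame)))
    frame["swapped"] = int(swapped)
    frame["response"] = ""
    frame = frame[TRIAL_COLUMNS]
    return ParticipantSet(
        participant_id=participant_id,
        trials=frame,
        catch_positions=tuple(catch_positions),
        swapped_copy_of=swapped_copy_of,
    )


def build_participant_sets(
    design: TripletDesign,
    reps: int = 4,
    swapped_reps: int = 2,
    set_size: int = 87,
    catch_positions: Sequence[int] | None = None,
    n_practice: int = DEFAULT_N_PRACTICE,
    seed: int = 0,
) -> list[ParticipantSet]:
    """Replicate the design ``reps`` times and package it into participant
    trial sets.

    The unswapped repetitions are partitioned into sets of ``set_size``
    trials; each set gets exactly one swapped copy (match sides exchanged),
    which supplies the ``swapped_reps`` swapped repetitions.  Catch trials
    duplicate the target as one match and sit at fixed 1-indexed positions
    within the presented sequence; practice trials precede it and are
    flagged.  All analyses downstream drop catch and practice rows.
    """
    if reps < swapped_reps:
        raise ParameterError("reps must be >= swapped_reps")
    if swapped_reps != 0 and reps != 2 * swapped_reps:
        raise ConfigurationError(
            "swapped sets are one-to-one copies of unswapped sets, which requires "
            "reps == 2 * swapped_reps (or swapped_reps == 0)"
        )
    if catch_positions is None:
        # canonical positions (40, 65, 84 of 90) scaled to the presented length
        n_presented = set_size + len(DEFAULT_CATCH_POSITIONS)
        catch_positions = tuple(
            sorted({max(1, round(p * n_presented / 90)) for p in DEFAULT_CATCH_POSITIONS})
        )
    unswapped_reps = reps - swapped_reps
    n_instances = len(design) * unswapped_reps
    if n_instances % set_size != 0:
        divisors = [d for d in range(set_size, 0, -1) if n_instances % d == 0]
        raise ConfigurationError(
            f"{len(design)} triplets x {unswapped_reps} unswapped reps = {n_instances} "
            f"trials not divisible by set_size {set_size}; nearest compatible set_size "
            f"is {divisors[0]}"
        )
    max_pos = set_size + len(catch_positions)
    if any(not 1 <= p <= max_pos for p in catch_positions):
        raise ConfigurationError(f"catch positions must lie in [1, {max_pos}]")

    rng = np.random.default_rng(seed)
    chunks = _partition_without_duplicates(design.triplets, unswapped_reps, set_size, rng)

    sets: list[ParticipantSet] = []
    for ci, chunk in enumerate(chunks):
        base_id = f"set{ci:02d}"
        experimental = []
        for trip in chunk:
            if rng.random() < 0.5:
                experimental.append((trip, trip.match_a, trip.match_b))
            else:
                experimental.append((trip, trip.match_b, trip.match_a))
        practice = []
        for _ in range(n_practice):
            t, a, b = rng.choice(design.n_items, size=3, replace=False)
            practice.append((Triplet.make(int(t), int(a), int(b)), int(a), int(b)))
        catch = []
        for _ in catch_positions:
            t, other = rng.choice(design.n_items, size=2, replace=False)
            if rng.random() < 0.5:
                catch.append((int(t), int(t), int(other)))
            else:
                catch.append((int(t), int(other), int(t)))
        unswapped = _set_frame(base_id, experimental, practice, catch, catch_positions, False, None)
        sets.append(unswapped)
        if swapped_reps:
            sets.append(
                _set_frame(base_id + "s", experimental, practice, catch, catch_positions, True, base_id)
            )
    return sets


def trials_table(sets: Sequence[ParticipantSet]) -> pd.DataFrame:
    """Concatenate participant sets into one flat trial table."""
    return pd.concat([s.trials for s in sets], ignore_index=True)


def experimental_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop catch and practice rows; the analysis-facing view of a table."""
    mask = (trials["is_catch"] == 0) & (trials["is_practice"] == 0)
    return trials.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


def verify_design(trials: pd.DataFrame, reps: int | None = None) -> dict:
    """Balance report over a trial table (catch/practice rows excluded).

    Reports per-item target-role and match-role counts, per-target partner
    count ranges in the base (deduplicated) design, duplicate triplets
    (combinations appearing more often than the repetition count), and a
    ``balanced`` verdict: target counts within a spread of one repetition
    and no duplicates.
    """
    exp = experimental_trials(trials)
    n_items = int(
        max(exp["target"].max(), exp["match_left"].max(), exp["match_right"].max())
    ) + 1
    target_counts = exp["target"].value_counts().reindex(range(n_items), fill_value=0)
    match_counts = (
        exp["match_left"].value_counts().reindex(range(n_items), fill_value=0)
        + exp["match_right"].value_counts().reindex(range(n_items), fill_value=0)
    )

    combos: dict[Triplet, int] = {}
    for t, l, r in zip(exp["target"], exp["match_left"], exp["match_right"]):
        trip = Triplet.make(int(t), int(l), int(r))
        combos[trip] = combos.get(trip, 0) + 1
    counts = np.array(list(combos.values()))
    if reps is None:
        values, freq = np.unique(counts, return_counts=True)
        reps = int(values[np.argmax(freq)])
    duplicates = sorted(t for t, c in combos.items() if c > reps)

    partner_ranges: dict[int, tuple[int, int]] = {}
    for target in range(n_items):
        pc: dict[int, int] = {}
        for trip in combos:
            if trip.target == target:
                pc[trip.match_a] = pc.get(trip.match_a, 0) + 1
                pc[trip.match_b] = pc.get(trip.match_b, 0) + 1
        if pc:
            partner_ranges[target] = (min(pc.values()), max(pc.values()))

    spread_ok = int(target_counts.max() - target_counts.min()) <= reps
    return {
        "n_items": n_items,
        "n_trials": len(exp),
        "reps": reps,
        "target_counts": target_counts.to_dict(),
        "target_count_range": (int(target_counts.min()), int(target_counts.max())),
        "match_counts": match_counts.to_dict(),
        "match_count_range": (int(match_counts.min()), int(match_counts.max())),
        "partner_count_ranges": partner_ranges,
        "duplicates": duplicates,
        "balanced": spread_ok and not duplicates,
    }


def all_triplets(n_items: int) -> list[Triplet]:
    """Exhaustive enumeration of every unique (target, match-pair) triplet."""
    out = []
    for target in range(n_items):
        others = [i for i in range(n_items) if i != target]
        for a, b in itertools.combinations(others, 2):
            out.append(Triplet.make(target, a, b))
    return out
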