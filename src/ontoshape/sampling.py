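"""Stratified signature sampling with largest-remainder seat allocation.

A signature of size ``n`` is drawn from the terminology so that the number of
seeds per sub-hierarchy follows a target weight vector as closely as integers
allow, with every sub-hierarchy receiving at least one seed (the rule that
keeps the rebalancing update well-defined: a stratum with zero seeds could
yield a module frequency of zero and an undefined scaling factor).

Seats are apportioned by the largest-remainder (Hamilton) method subject to a
floor of one seat and a ceiling of the stratum's class count; within each
stratum, classes are sampled uniformly without replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ArgumentError
from .model import OntologyGraph


@dataclass(frozen=True)
class Signature:
    """A seed set together with the stratum weights that produced it."""

    classes: frozenset[str]
    weights: dict[str, float]
    allocation: dict[str, int]
    size: int
    rng_seed: int


def allocate_seats(
    weights: Mapping[str, float], n: int, capacity: Mapping[str, int]
) -> dict[str, int]:
    """Integer seats per stratum: largest remainder, floor 1, capped capacity.

    Starts from the clipped integer parts of the exact quotas ``n * w_k`` and
    then adds (removes) single seats to (from) the stratum whose seat count is
    furthest below (above) its quota, ties broken by stratum id.  Each step is
    the best unit move for the objective sum_k |seats_k - n*w_k|, which is
    separable convex, so the greedy result attains the optimum.
    """
    keys = sorted(weights)
    if not keys:
        raise ArgumentError("no strata")
    if set(capacity) < set(keys):
        raise ArgumentError("capacity missing for some strata")
    k = len(keys)
    if n < k:
        raise ArgumentError(f"n = {n} is smaller than the number of strata ({k})")
    if any(weights[key] < 0 for key in keys):
        raise ArgumentError("weights must be non-negative")
    wsum = float(sum(weights[key] for key in keys))
    if not math.isclose(wsum, 1.0, abs_tol=1e-6):
        raise ArgumentError(f"weights must sum to 1 (got {wsum:.6g})")
    if any(capacity[key] < 1 for key in keys):
        raise ArgumentError("every stratum capacity must be >= 1")
    if sum(capacity[key] for key in keys) < n:
        raise ArgumentError("total capacity is smaller than n")

    quota = {key: n * weights[key] / wsum for key in keys}
    seats = {
        key: min(max(1, int(math.floor(quota[key]))), capacity[key]) for key in keys
    }
    total = sum(seats.values())
    while total > n:
        key = min(
            (key for key in keys if seats[key] > 1),
            key=lambda key: (quota[key] - seats[key], key),
        )
        seats[key] -= 1
        total -= 1
    while total < n:
        key = max(
            (key for key in keys if seats[key] < capacity[key]),
            key=lambda key: (quota[key] - seats[key], _RevStr(key)),
        )
        seats[key] += 1
        total += 1
    return seats


class _RevStr(str):
    """Reverse string ordering, so max() tie-breaks to the smallest id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


def sample_signature(
    graph: OntologyGraph, weights: Mapping[str, float], n: int, rng_seed: int
) -> Signature:
    """Draw a stratified signature of ``n`` classes (deterministic per seed)."""
    strata: dict[str, list[str]] = {sh: [] for sh in graph.subhierarchies()}
    for cid, sh in graph.subhierarchy_of.items():
        strata[sh].append(cid)
    unknown = sorted(set(weights) - set(strata))
    if unknown:
        raise ArgumentError("weights name unknown sub-hierarchies: " + ", ".join(unknown))
    if set(weights) != set(strata):
        raise ArgumentError("weights must cover every sub-hierarchy")
    capacity = {sh: len(ids) for sh, ids in strata.items()}
    allocation = allocate_seats(weights, n, capacity)
    rng = np.random.default_rng(rng_seed)
    chosen: set[str] = set()
    for sh in sorted(strata):
        pool = sorted(strata[sh])
        picks = rng.choice(len(pool), size=allocation[sh], replace=False)
        chosen.update(pool[i] for i in picks)
    return Signature(frozenset(chosen), dict(weights), allocation, n, rng_seed)


def weights_from_freqs(freqs: Mapping[str, float]) -> dict[str, float]:
    """Normalize percent frequencies into fractional weights summing to 1."""
    total = sum(freqs.values())
    if total <= 0:
        raise ArgumentError("frequencies must have a positive sum")
    return {k: v / total for k, v in freqs.items()}
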