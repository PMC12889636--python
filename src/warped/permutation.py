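"""Whole-pedigree sex-permutation null for Warp.

Shuffling the sex labels over a fixed topology produces pedigrees of the
same size, depth and overall sex ratio but with no heritable signal; the
permuted pedigrees deliberately admit extreme outcomes such as a
female-labelled individual in a father role (permissive mode).  Three
empirical p-values compare the true run against the permuted runs:

``max_likelihood``
    Fraction of permutations whose highest posterior exceeds the true
    run's highest posterior.
``z_max``
    The same comparison after standardizing each run's posteriors to
    z-scores (guards against run-to-run shifts in location/scale).
``focal_rank``
    Fraction of permutations in which the true top individual ranks
    strictly better than its rank in the true run.

All counting rules use a strict ">" (count/N, not (count+1)/(N+1)), so
p = 0 is attainable; pass ``add_one=True`` for the add-one convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .bp import CarrierPosterior, ModelParams, run_warp
from .pedigree import Pedigree


@dataclass
class PermutationResult:
    method: str
    observed_stat: float
    permuted_stats: list[float]
    n_permutations: int
    p_value: float
    seed: Optional[int] = None
    focal_id: Optional[str] = None


def permute_sexes(ped: Pedigree, seed: int) -> Pedigree:
    """Seeded uniform shuffle of the sex-label multiset over fixed topology.

    Sex-unknown labels are shuffled along with the rest.  The result is a
    permissive-mode pedigree with identical individuals and parent edges.
    """
    rng = np.random.default_rng(seed)
    ids = ped.ids
    labels = [ped[i].sex for i in ids]
    perm = rng.permutation(len(ids))
    shuffled = {ids[k]: labels[perm[k]] for k in range(len(ids))}
    return ped.with_sexes(shuffled, provenance=f"sex-permuted(seed={seed})")


def _count_p(observed: float, permuted: Sequence[float], add_one: bool) -> float:
    exceed = sum(1 for s in permuted if s > observed)
    if add_one:
        return (exceed + 1) / (len(permuted) + 1)
    return exceed / len(permuted)


def max_likelihood_pvalue(
    true_post: CarrierPosterior,
    perm_posts: Sequence[CarrierPosterior],
    add_one: bool = False,
) -> PermutationResult:
    """p = fraction of permutations whose maximum posterior is strictly
    greater than the true maximum."""
    if not perm_posts:
        raise ValueError("at least one permutation is required")
    observed = true_post.max_value()
    permuted = [p.max_value() for p in perm_posts]
    return PermutationResult(
        method="max_likelihood",
        observed_stat=observed,
        permuted_stats=permuted,
        n_permutations=len(permuted),
        p_value=_count_p(observed, permuted, add_one),
    )


def _max_z(post: CarrierPosterior, label: str) -> float:
    vals = np.fromiter(post.values.values(), dtype=float)
    sd = vals.std()  # population sd; the run is the whole population
    if sd == 0.0:
        raise ValueError(
            f"zero standard deviation of posteriors in {label}: "
            "z-normalization undefined"
        )
    return float((vals.max() - vals.mean()) / sd)


def z_max_pvalue(
    true_post: CarrierPosterior,
    perm_posts: Sequence[CarrierPosterior],
    add_one: bool = False,
) -> PermutationResult:
    """p from comparing per-run standardized maxima (z of the top
    posterior within each run)."""
    if not perm_posts:
        raise ValueError("at least one permutation is required")
    observed = _max_z(true_post, "the true run")
    permuted = [
        _max_z(p, f"permutation {k}") for k, p in enumerate(perm_posts)
    ]
    return PermutationResult(
        method="z_max",
        observed_stat=observed,
        permuted_stats=permuted,
        n_permutations=len(permuted),
        p_value=_count_p(observed, permuted, add_one),
    )


def _rank(post: CarrierPosterior, focal_id: str) -> int:
    # competition ranking: rank 1 is the top posterior; ties -> minimum rank
    if focal_id not in post.values:
        raise KeyError(f"focal individual {focal_id!r} missing from a run")
    focal = post.values[focal_id]
    return 1 + sum(1 for v in post.values.values() if v > focal)


def focal_rank_pvalue(
    focal_id: str,
    true_post: CarrierPosterior,
    perm_posts: Sequence[CarrierPosterior],
    add_one: bool = False,
) -> PermutationResult:
    """p = fraction of permutations in which the focal individual ranks
    strictly better (smaller rank) than in the true run."""
    if not perm_posts:
        raise ValueError("at least one permutation is required")
    true_rank = _rank(true_post, focal_id)
    perm_ranks = [_rank(p, focal_id) for p in perm_posts]
    better = sum(1 for r in perm_ranks if r < true_rank)
    if add_one:
        p = (better + 1) / (len(perm_ranks) + 1)
    else:
        p = better / len(perm_ranks)
    return PermutationResult(
        method="focal_rank",
        observed_stat=float(true_rank),
        permuted_stats=[float(r) for r in perm_ranks],
        n_permutations=len(perm_ranks),
        p_value=p,
        focal_id=focal_id,
    )


def run_permutation_suite(
    ped: Pedigree,
    params: ModelParams,
    n_perm: int = 1000,
    seed: int = 0,
    tol: float = 1e-9,
    max_sweeps: int = 100,
    add_one: bool = False,
) -> dict[str, PermutationResult]:
    """Run Warp on the true pedigree and on ``n_perm`` sex permutations.

    Permuted runs use the same model parameters and convergence settings
    as the true run; permutation seeds are derived deterministically from
    ``seed``.  The focal individual for the rank comparison is the true
    run's argmax.  Returns the three results keyed by method name.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    true_post = run_warp(ped, params, tol=tol, max_sweeps=max_sweeps)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_perm) >> 1
    perm_posts = []
    for k in range(n_perm):
        perm_ped = permute_sexes(ped, int(child_seeds[k]))
        post = run_warp(perm_ped, params, tol=tol, max_sweeps=max_sweeps)
        if not post.converged:
            warnings.warn(
                f"permutation {k} did not converge in {max_sweeps} sweeps; "
                "included anyway",
                stacklevel=2,
            )
        perm_posts.append(post)
    results = {
        "max_likelihood": max_likelihood_pvalue(true_post, perm_posts, add_one),
        "z_max": z_max_pvalue(true_post, perm_posts, add_one),
        "focal_rank": focal_rank_pvalue(
            true_post.max_id(), true_post, perm_posts, add_one
        ),
    }
    for r in results.values():
        r.seed = seed
    return results
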