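"""Perturbation-based confidence intervals for ancestral state estimates.

Point estimates come from the ridge rate model fitted to the full data.
Uncertainty from phylogenetic error and taxon-sampling bias is assessed by
refitting the model on perturbed replicates of the dataset: each replicate
drops a fraction of the tips, swaps the tree positions of a fraction of the
survivors (only within the same clade, so swaps stay taxonomically
plausible), and jitters a fraction of the internal node ages.  Replicates
whose selected ridge penalty indicates convergence to a degenerate optimum
(normalized λ′ = λ/(1+λ) below a validity floor) are discarded, and the
loop continues until a target number of valid replicates is reached.  The
CI of a node is the empirical 2.5–97.5% quantile band of its estimates
across replicates, matching each original node to the MRCA of its
surviving descendants in every replicate.

The procedure is an uncertainty heuristic, not an exact confidence
interval; the point estimate is not guaranteed to lie inside the band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ridge import RidgeRateModel
from .tree import DatedTree, mrca

logger = logging.getLogger(__name__)

__all__ = ["PerturbationConfig", "perturb_replicate", "run_ci", "CIResult"]


@dataclass
class PerturbationConfig:
    """Knobs of the replicate-perturbation protocol.

    drop_frac : fraction of tips discarded per replicate (default 0.20)
    swap_frac : fraction of remaining tips whose positions are exchanged,
        pairs drawn within the same clade (default 0.10)
    age_frac : fraction of internal nodes whose age is multiplied by a
        U(0.5, 1.5) factor, clamped to keep parent older than children
        (default 0.10)
    lambda_min : validity floor on the normalized ridge penalty λ/(1+λ);
        replicates below it are discarded (default 0.9)
    n_valid : number of valid replicates to accumulate (default 100)
    ci : lower/upper quantiles of the reported band
    """

    drop_frac: float = 0.20
    swap_frac: float = 0.10
    age_frac: float = 0.10
    lambda_min: float = 0.9
    n_valid: int = 100
    ci: tuple[float, float] = (0.025, 0.975)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.drop_frac < 1):
            raise ValueError("drop_frac must lie in [0, 1)")
        for name in ("swap_frac", "age_frac"):
            val = getattr(self, name)
            if not (0 <= val <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_valid < 1:
            raise ValueError("n_valid must be >= 1")
        if not (0 <= self.ci[0] < self.ci[1] <= 1):
            raise ValueError("ci bounds must be ordered within [0, 1]")


def perturb_replicate(
    tree: DatedTree,
    traits: Mapping[str, float] | pd.Series,
    clade_map: Mapping[str, str],
    config: PerturbationConfig,
    rng: np.random.Generator,
) -> tuple[DatedTree, pd.Series]:
    """One perturbed (tree, traits) replicate.

    Traits travel with the tip label, so exchanging the labels of two tips
    exchanges their positions in the tree.  A clade with fewer than two
    remaining tips contributes no swaps.
    """
    traits = pd.Series(dict(traits) if not isinstance(traits, pd.Series) else traits)
    tree = tree.copy()
    names = tree.tip_names()
    n = len(names)

    # 1. drop tips
    n_drop = int(np.floor(config.drop_frac * n))
    if n_drop and n - n_drop >= 3:
        doomed = list(rng.choice(names, size=n_drop, replace=False))
        tree.drop_tips(doomed)

    # 2. within-clade position swaps
    remaining = tree.tip_names()
    n_swap = int(np.floor(config.swap_frac * len(remaining)))
    if n_swap >= 2:
        pairs: list[tuple[str, str]] = []
        by_clade: dict[str, list[str]] = {}
        for tip in remaining:
            clade = clade_map.get(tip)
            if clade is not None:
                by_clade.setdefault(clade, []).append(tip)
        for members in by_clade.values():
            members = list(members)
            rng.shuffle(members)
            pairs.extend(
                (members[i], members[i + 1])
                for i in range(0, len(members) - 1, 2)
            )
        perm = rng.permutation(len(pairs))
        chosen = [pairs[i] for i in perm[: n_swap // 2]]
        for a, b in chosen:
            node_a, node_b = tree.find_tip(a), tree.find_tip(b)
            node_a.name, node_b.name = node_b.name, node_a.name

    # 3. jitter internal node ages
    ages = tree.ages()
    internals = [nd for nd in tree.internal_nodes()]
    n_age = int(np.floor(config.age_frac * len(internals)))
    if n_age:
        picked = rng.choice(len(internals), size=n_age, replace=False)
        for idx in picked:
            node = internals[idx]
            proposal = ages[node] * rng.uniform(0.5, 1.5)
            lo = max((ages[c] for c in node.children), default=0.0)
            hi = ages[node.parent] if node.parent is not None else np.inf
            margin = 1e-9 * max(ages[tree.root], 1.0)
            ages[node] = float(np.clip(proposal, lo + margin, hi - margin))
        tree.set_ages(ages)

    return tree, traits.loc[tree.tip_names()]


@dataclass
class CIResult:
    """Ancestral point estimates with perturbation-quantile bands.

    ``table`` rows are keyed by the node's descendant tip set in the
    original tree ('|'-joined sorted labels) and report the full-data point
    estimate, the lower/upper quantiles across valid replicates, and the
    number of replicates in which the node could be matched.
    """

    table: pd.DataFrame
    n_valid: int
    n_attempts: int
    lambda_normalized: list[float] = field(default_factory=list)

    def for_node(self, key: str) -> pd.Series:
        return self.table.loc[key]


def run_ci(
    tree: DatedTree,
    traits: Mapping[str, float] | pd.Series,
    clade_map: Mapping[str, str],
    config: PerturbationConfig | None = None,
    trait_name: str = "trait",
) -> CIResult:
    """Perturb → refit until ``n_valid`` valid replicates; quantile CIs.

    Raises ``RuntimeError`` if valid replicates are not reached within
    ``20 × n_valid`` attempts (the λ′ validity floor rejects too much).
    """
    config = config or PerturbationConfig()
    rng = np.random.default_rng(config.seed)
    traits = pd.Series(dict(traits) if not isinstance(traits, pd.Series) else traits)

    point_fit = RidgeRateModel(tree, traits, trait_name=trait_name).fit()
    point_states = point_fit.ancestral_states()
    focal = {
        tree.clade_key(node): tree._tipset(node)
        for node in tree.internal_nodes()
    }
    collected: dict[str, list[float]] = {key: [] for key in focal}

    n_valid = 0
    attempts = 0
    lambdas: list[float] = []
    max_attempts = 20 * config.n_valid
    while n_valid < config.n_valid:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"only {n_valid}/{config.n_valid} valid replicates after "
                f"{attempts} attempts; λ' validity floor {config.lambda_min} "
                "rejects too many fits"
            )
        attempts += 1
        rep_tree, rep_traits = perturb_replicate(tree, traits, clade_map, config, rng)
        fit = RidgeRateModel(rep_tree, rep_traits, trait_name=trait_name).fit()
        if fit.lambda_normalized < config.lambda_min:
            continue
        n_valid += 1
        lambdas.append(fit.lambda_normalized)
        rep_states = fit.node_states()
        rep_tips = set(rep_tree.tip_names())
        for key, tipset in focal.items():
            surviving = sorted(tipset & rep_tips)
            if len(surviving) < 2:
                continue
            node = mrca(rep_tree, surviving)
            collected[key].append(rep_states[node])

    rows = []
    for key, values in collected.items():
        arr = np.asarray(values)
        if arr.size:
            lo = float(np.quantile(arr, config.ci[0]))  # type-7 interpolation
            hi = float(np.quantile(arr, config.ci[1]))
        else:
            lo = hi = np.nan
        rows.append(
            {
                "node": key,
                "n_tips": len(focal[key]),
                "point": point_states[key],
                "lo": lo,
                "hi": hi,
                "n_replicates": int(arr.size),
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    return CIResult(
        table=table,
        n_valid=n_valid,
        n_attempts=attempts,
        lambda_normalized=lambdas,
    )
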