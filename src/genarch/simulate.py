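"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators cover everything the analysis consumes:

* ``simulate_genome`` — a GFF3 genome annotation whose gene structures are
  drawn from controlled distributions: a Bernoulli intronless fraction,
  a shifted-Poisson exon count for intron-bearing genes, and log-normal
  exon/intron lengths (heavy-tailed, like real intron-length
  distributions; an optional two-component log-normal mixture emulates
  genomes with two distinct intron populations).  By default CDS and exon
  intervals coincide (pure-coding genes) so the extraction arithmetic has
  a closed form; optional UTR decoration adds non-coding exon sequence to
  exercise CDS-span trimming, and alternative shorter-CDS transcripts
  exercise canonical-transcript selection.
* ``simulate_tree`` — pure-birth (Yule) ultrametric trees rescaled to a
  chosen root age in Myr.
* ``simulate_bm`` — Brownian-motion trait evolution with optional
  per-clade rate multipliers; every node state is recorded.

``build_study_fixture`` strings them together into a small end-to-end
study: species-level gene-structure traits evolve on a simulated tree, and
each species' genome generator is tuned (by log-normal mean matching) so
that its expected extraction summary equals the species' simulated trait
values, with the truth retained for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genes import GeneRecord, SpeciesSummary, summarize_species, write_gff3, TranscriptModel
from .tree import DatedTree, TreeNode, assign_branches

__all__ = [
    "GenomeSpec",
    "TraitSimSpec",
    "SimTruth",
    "simulate_tree",
    "simulate_bm",
    "simulate_genome",
    "build_study_fixture",
]


@dataclass
class GenomeSpec:
    """Parameters of a synthetic genome annotation.

    Intron-bearing genes draw their exon count as ``2 + Poisson(mean−2)``
    (so every such gene has at least one intron); exon and intron lengths
    are log-normal with the given median and log-sd (natural log).  With
    ``intron_len_mixture = (median2, weight)`` intron lengths come from a
    two-component log-normal mixture sharing ``intron_len_sdlog``.
    """

    n_genes: int = 1000
    exon_count_mean: float = 5.0  # mean exons per intron-bearing gene (≥2)
    exon_len_median: float = 150.0
    exon_len_sdlog: float = 0.4
    intron_len_median: float = 800.0
    intron_len_sdlog: float = 0.8
    intronless_fraction: float = 0.15
    n_seqs: int = 4
    alt_transcript_prob: float = 0.0
    utr_decoration: bool = False
    fixed_exon_count: int | None = None  # overrides the Poisson law (≥2)
    intron_len_mixture: tuple[float, float] | None = None  # (median2, weight2)
    intergenic_gap: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.exon_count_mean < 2:
            raise ValueError("exon_count_mean must be >= 2 (intron-bearing genes)")
        if not (0 <= self.intronless_fraction <= 1):
            raise ValueError("intronless_fraction must lie in [0, 1]")

    # analytic expectations used by recovery tests -----------------------
    def expected_mean_intron_len(self) -> float:
        bulk = self.intron_len_median * math.exp(self.intron_len_sdlog**2 / 2)
        if self.intron_len_mixture is None:
            return bulk
        med2, w2 = self.intron_len_mixture
        second = med2 * math.exp(self.intron_len_sdlog**2 / 2)
        return (1 - w2) * bulk + w2 * second

    def expected_mean_n_introns(self) -> float:
        if self.fixed_exon_count is not None:
            per_gene = float(max(2, self.fixed_exon_count) - 1)
        else:
            per_gene = 1.0 + (self.exon_count_mean - 2.0)
        return (1 - self.intronless_fraction) * per_gene


@dataclass
class TraitSimSpec:
    """Brownian-motion trait simulation parameters (single or shifted rate)."""

    sigma2: float = 0.01
    root: float = 0.0
    clade_rate_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if any(m <= 0 for m in self.clade_rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")


@dataclass
class SimTruth:
    """Ground truth retained by the generators."""

    node_states: dict[str, float] = field(default_factory=dict)
    branch_multipliers: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    species_summary: SpeciesSummary | None = None
    species_targets: pd.DataFrame | None = None


# ----------------------------------------------------------------- trees


def simulate_tree(
    n_tips: int, depth_myr: float, rng: np.random.Generator | int | None = None
) -> DatedTree:
    """Pure-birth (Yule) ultrametric tree rescaled to root age ``depth_myr``."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(rng)
    root = TreeNode(name=None)
    t = 0.0
    birth: dict[TreeNode, float] = {root: 0.0}
    active = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    birth[active[0]] = birth[active[1]] = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(int(rng.integers(len(active))))
        birth[parent] = t  # becomes an internal node splitting at time t
        kids = [parent.add_child(TreeNode()), parent.add_child(TreeNode())]
        for kid in kids:
            birth[kid] = t
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / len(active))
    scale = depth_myr / t_end if t_end > 0 else 1.0

    tree = DatedTree(root)
    tips = tree.tips()
    for i, tip in enumerate(tips):
        tip.name = f"sp{i + 1:03d}"
    for node in tree.nodes():
        if node.parent is None:
            continue
        end = t_end if node.is_leaf() else birth[node]
        node.length = (end - birth.get(node.parent, 0.0)) * scale
    return tree


def simulate_bm(
    tree: DatedTree,
    spec: TraitSimSpec,
    rng: np.random.Generator | int | None = None,
    clade_map: Mapping[str, str] | None = None,
) -> tuple[pd.Series, SimTruth]:
    """Brownian trait evolution along the tree; all node states recorded.

    ``clade_rate_multipliers`` scale σ² on the branches assigned to each
    clade (via MRCA branch assignment), emulating rate shifts.
    """
    rng = np.random.default_rng(rng)
    multipliers: dict[TreeNode, float] = {b: 1.0 for b in tree.branches()}
    if spec.clade_rate_multipliers:
        if clade_map is None:
            raise ValueError("clade_map required when rate multipliers are given")
        labels = assign_branches(tree, clade_map)
        for branch, label in labels.items():
            multipliers[branch] = spec.clade_rate_multipliers.get(label, 1.0)

    states: dict[TreeNode, float] = {tree.root: spec.root}
    for node in tree.nodes():
        if node.parent is None:
            continue
        var = spec.sigma2 * multipliers[node] * node.length
        states[node] = states[node.parent] + (
            rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0
        )
    tips = pd.Series(
        {n.name: states[n] for n in tree.tips()}, name="trait"
    ).loc[tree.tip_names()]
    truth = SimTruth(
        node_states={tree.clade_key(n): v for n, v in states.items()},
        branch_multipliers={
            tree.clade_key(b): m for b, m in multipliers.items()
        },
        params={"sigma2": spec.sigma2, "root": spec.root},
    )
    return tips, truth


# ---------------------------------------------------------------- genomes


def _lognormal_int(rng, median: float, sdlog: float, minimum: int = 1) -> int:
    return max(minimum, int(round(rng.lognormal(math.log(median), sdlog))))


def _draw_gene_lengths(spec: GenomeSpec, rng) -> tuple[list[int], list[int]]:
    """(exon lengths, intron lengths) of one gene."""
    if rng.random() < spec.intronless_fraction:
        return [_lognormal_int(rng, spec.exon_len_median, spec.exon_len_sdlog)], []
    if spec.fixed_exon_count is not None:
        k = max(2, spec.fixed_exon_count)
    else:
        k = 2 + rng.poisson(spec.exon_count_mean - 2.0)
    exons = [
        _lognormal_int(rng, spec.exon_len_median, spec.exon_len_sdlog)
        for _ in range(k)
    ]
    introns = []
    for _ in range(k - 1):
        if spec.intron_len_mixture is not None and rng.random() < spec.intron_len_mixture[1]:
            median = spec.intron_len_mixture[0]
        else:
            median = spec.intron_len_median
        introns.append(_lognormal_int(rng, median, spec.intron_len_sdlog))
    return exons, introns


def simulate_genome(
    spec: GenomeSpec, rng: np.random.Generator | int | None = None
) -> tuple[str, SimTruth]:
    """A GFF3 document plus the exact per-gene truth used to build it."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    transcripts: list[TranscriptModel] = []
    records: list[GeneRecord] = []
    cursors = {f"chr{i + 1}": 1 for i in range(spec.n_seqs)}
    seq_names = list(cursors)

    for g in range(spec.n_genes):
        seq = seq_names[g % spec.n_seqs]
        exon_lens, intron_lens = _draw_gene_lengths(spec, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[seq] + spec.intergenic_gap

        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el - 1))
            if i < len(intron_lens):
                pos = pos + el + intron_lens[i]
            else:
                pos = pos + el
        cds = list(exons)

        if spec.utr_decoration:
            # extend the first/last exon with non-coding flanks and add a
            # detached UTR exon upstream; trimming must remove all of it
            flank = _lognormal_int(rng, spec.exon_len_median / 2, 0.3)
            utr_len = _lognormal_int(rng, spec.exon_len_median, 0.3)
            first = exons[0]
            last = exons[-1]
            lifted_start = max(1, first[0] - flank)
            exons = [(lifted_start, first[1])] + exons[1:]
            exons[-1] = (exons[-1][0], last[1] + flank)
            utr_exon_end = lifted_start - 50 - 1
            utr_exon_start = utr_exon_end - utr_len + 1
            if utr_exon_start > cursors[seq]:
                exons = [(utr_exon_start, utr_exon_end)] + exons

        gene_id = f"g{g + 1:05d}"
        tx_id = f"{gene_id}.t1"
        transcripts.append(
            TranscriptModel(
                transcript_id=tx_id, gene_id=gene_id, seq_id=seq,
                strand=strand, exons=exons, cds=cds,
            )
        )
        if spec.alt_transcript_prob and len(cds) >= 2 and (
            rng.random() < spec.alt_transcript_prob
        ):
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t2", gene_id=gene_id, seq_id=seq,
                    strand=strand, exons=exons[:-1] if not spec.utr_decoration
                    else list(cds[:-1]), cds=cds[:-1],
                )
            )

        total_exon = sum(exon_lens)
        total_intron = sum(intron_lens)
        records.append(
            GeneRecord(
                gene_id=gene_id, transcript_id=tx_id,
                n_introns=len(intron_lens), intron_lengths=list(intron_lens),
                total_intron_len=total_intron, total_exon_len=total_exon,
                intron_ratio=total_intron / total_exon,
                intronless=not intron_lens,
            )
        )
        cursors[seq] = max(b for _, b in exons)

    regions = {seq: cursors[seq] + spec.intergenic_gap for seq in seq_names}
    gff3 = write_gff3(transcripts, sequence_regions=regions)
    genome_size = sum(regions.values())
    truth = SimTruth(
        params={
            "spec": spec,
            "expected_mean_intron_len": spec.expected_mean_intron_len(),
            "expected_mean_n_introns": spec.expected_mean_n_introns(),
            "genome_size": genome_size,
        },
        species_summary=summarize_species(records, genome_size, "truth"),
    )
    truth.params["records"] = records
    return gff3, truth


# ------------------------------------------------------------ full study


def build_study_fixture(
    n_species: int = 16,
    tree_depth: float = 500.0,
    trait_specs: Mapping[str, TraitSimSpec] | None = None,
    n_genes: int = 400,
    intronless_fraction: float = 0.15,
    min_clade_size: int = 1,
    rng: np.random.Generator | int | None = None,
) -> tuple[DatedTree, dict[str, str], dict[str, str], SimTruth]:
    """End-to-end synthetic study: tree, per-species GFF3s, clades, truth.

    Species-level traits — log10 mean intron ratio, log10 mean intron
    length, and mean intron count — evolve by BM on a Yule tree (rate
    multipliers apply to the clades named in each spec).  The two subtrees
    of the root define the clades ``cladeA``/``cladeB``.  Each species'
    genome generator is then tuned so its expected extraction summary hits
    the simulated trait values, using the consistency constraint
    ``ratio ≈ mean_n_introns · mean_intron_len / mean_total_exon_len`` to
    derive the exon-length scale.  Raises ``ValueError`` when a species'
    simulated trait combination implies an infeasible genome (fewer than
    one intron per intron-bearing gene, or sub-1-bp exons).
    """
    rng = np.random.default_rng(rng)
    if trait_specs is None:
        trait_specs = {
            "log10_mean_intron_ratio": TraitSimSpec(sigma2=2e-4, root=0.3),
            "log10_mean_intron_len": TraitSimSpec(sigma2=2e-4, root=3.0),
            "mean_n_introns": TraitSimSpec(sigma2=2e-3, root=5.0),
        }
    required = {
        "log10_mean_intron_ratio",
        "log10_mean_intron_len",
        "mean_n_introns",
    }
    if set(trait_specs) != required:
        raise ValueError(f"trait_specs must cover exactly {sorted(required)}")

    if not 1 <= min_clade_size <= n_species // 2:
        raise ValueError("min_clade_size must lie in [1, n_species/2]")
    while True:
        tree = simulate_tree(n_species, tree_depth, rng)
        left = tree.root.children[0]
        n_left = len(tree._tipset(left))
        if min(n_left, n_species - n_left) >= min_clade_size:
            break
    clade_map = {}
    for tip in tree.tips():
        in_left = tip.name in tree._tipset(left)
        clade_map[tip.name] = "cladeA" if in_left else "cladeB"

    truth = SimTruth(params={"tree_depth": tree_depth, "n_genes": n_genes})
    traits: dict[str, pd.Series] = {}
    for name, spec in trait_specs.items():
        tips, t_truth = simulate_bm(tree, spec, rng, clade_map=clade_map)
        traits[name] = tips
        truth.node_states[name] = t_truth.node_states
        truth.branch_multipliers[name] = t_truth.branch_multipliers
        truth.params[name] = {"sigma2": spec.sigma2, "root": spec.root}

    gffs: dict[str, str] = {}
    targets = []
    for species in tree.tip_names():
        ratio = 10.0 ** traits["log10_mean_intron_ratio"][species]
        intron_len = 10.0 ** traits["log10_mean_intron_len"][species]
        n_introns = traits["mean_n_introns"][species]
        if n_introns <= (1 - intronless_fraction):
            raise ValueError(
                f"{species}: mean_n_introns {n_introns:.3g} implies fewer than "
                "one intron per intron-bearing gene; the trait combination is "
                "infeasible (ratio ≈ n_introns·intron_len/exon_len)"
            )
        per_gene_introns = n_introns / (1 - intronless_fraction)
        exon_count_mean = per_gene_introns + 1.0
        # ratio target is over all genes (intronless contribute 0):
        # (1-f)·(per-gene intron sum / exon sum) = ratio
        total_exon = (1 - intronless_fraction) * per_gene_introns * intron_len / ratio
        exon_len_sdlog = 0.3
        exon_len_mean = total_exon / ((1 - intronless_fraction) * exon_count_mean)
        if exon_len_mean < 1.5:
            raise ValueError(
                f"{species}: implied mean exon length {exon_len_mean:.3g} bp is "
                "infeasible; check trait consistency "
                "(ratio ≈ n_introns·intron_len/exon_len)"
            )
        intron_sdlog = 0.6
        spec = GenomeSpec(
            n_genes=n_genes,
            exon_count_mean=exon_count_mean,
            exon_len_median=exon_len_mean / math.exp(exon_len_sdlog**2 / 2),
            exon_len_sdlog=exon_len_sdlog,
            intron_len_median=intron_len / math.exp(intron_sdlog**2 / 2),
            intron_len_sdlog=intron_sdlog,
            intronless_fraction=intronless_fraction,
            n_seqs=2,
        )
        gff3, _ = simulate_genome(spec, rng)
        gffs[species] = gff3
        targets.append(
            {
                "species": species,
                "clade": clade_map[species],
                "target_mean_intron_ratio": ratio,
                "target_mean_intron_len": intron_len,
                "target_mean_n_introns": n_introns,
            }
        )
    truth.species_targets = pd.DataFrame(targets).set_index("species")
    return tree, gffs, clade_map, truth
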