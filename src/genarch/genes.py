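"""Gene-structure feature extraction from GFF3 genome annotations.

The unit of analysis is the *canonical transcript* of each protein-coding
gene: the splice variant with the largest summed CDS length.  Because UTR
annotation quality is uneven across genomes, every transcript is trimmed to
its CDS span (exons wholly outside the span are removed, partially
overlapping ones are clipped) before introns are inferred as the gaps
between consecutive exons.  Per-gene features — intron count, intron
lengths, total intron and exon lengths, and the intron ratio (total intron
length / total exon length; 0 for intronless genes) — are then aggregated
into per-species summaries and genome-wide feature distributions.

All coordinates are GFF3 1-based inclusive; an intron between exons ending
at ``prev_end`` and starting at ``next_start`` spans
``(prev_end+1, next_start-1)`` and has length ``next_start − prev_end − 1``.
"""

from __future__ import annotations

import io
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

__all__ = [
    "TranscriptModel",
    "Gene",
    "GeneRecord",
    "SpeciesSummary",
    "parse_annotations",
    "select_canonical",
    "trim_to_cds",
    "infer_introns",
    "compute_gene_record",
    "summarize_species",
    "genome_size_from_headers",
    "extract_species",
    "feature_distribution",
    "write_gff3",
]

# species-level means that are reported on a log10 scale as well
_LOG10_FIELDS = (
    "mean_intron_ratio",
    "mean_intron_len",
    "mean_total_intron_len",
    "mean_total_exon_len",
    "genome_size",
)


@dataclass
class TranscriptModel:
    """A transcript as a set of exon and CDS intervals on one sequence."""

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        for (a0, b0), (a1, b1) in zip(self.exons, self.exons[1:]):
            if a1 <= b0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    def total_cds_len(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)


@dataclass
class Gene:
    gene_id: str
    transcripts: list[TranscriptModel]


@dataclass
class GeneRecord:
    """Per-gene structure features of the (trimmed) canonical transcript."""

    gene_id: str
    transcript_id: str
    n_introns: int
    intron_lengths: list[int]
    total_intron_len: int
    total_exon_len: int
    intron_ratio: float
    intronless: bool


@dataclass
class SpeciesSummary:
    """Genome-wide means of gene-structure features for one species.

    ``mean_intron_len`` is the mean over the pooled genome-wide set of
    introns (not a mean of per-gene means); all other means are over genes,
    with intronless genes contributing ratio 0.  ``log10`` holds the log10
    of each length/ratio mean (never of the intron count); a mean of 0 or a
    genome with no introns yields a missing (NaN) log entry.
    """

    species_id: str
    n_genes: int
    mean_intron_ratio: float
    mean_intron_len: float
    mean_n_introns: float
    mean_total_intron_len: float
    mean_total_exon_len: float
    fraction_intronless: float
    genome_size: float
    log10: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        out = {
            "species_id": self.species_id,
            "n_genes": self.n_genes,
            "mean_intron_ratio": self.mean_intron_ratio,
            "mean_intron_len": self.mean_intron_len,
            "mean_n_introns": self.mean_n_introns,
            "mean_total_intron_len": self.mean_total_intron_len,
            "mean_total_exon_len": self.mean_total_exon_len,
            "fraction_intronless": self.fraction_intronless,
            "genome_size": self.genome_size,
        }
        for key, val in self.log10.items():
            out[f"log10_{key}"] = val
        return out


# ----------------------------------------------------------------- parsing


def _as_db(source, **kwargs):
    if isinstance(source, gffutils.FeatureDB):
        return source
    if hasattr(source, "read"):
        data, from_string = source.read(), True
    else:
        data = str(source)
        from_string = "\t" in data or "\n" in data
        if not from_string and not os.path.exists(data):
            raise IOError(f"GFF3 input not found: {data}")
    try:
        return gffutils.create_db(
            data,
            dbfn=":memory:",
            from_string=from_string,
            merge_strategy="create_unique",
            keep_order=True,
            **kwargs,
        )
    except Exception as exc:  # sqlite/parse failures
        raise IOError(f"could not read GFF3 input: {exc}") from exc


def parse_annotations(source, cds_as_exons: bool = False) -> list[Gene]:
    """Parse GFF3 into genes with their transcript models.

    ``source`` is a path, text stream, GFF3 string, or an existing
    :class:`gffutils.FeatureDB`.  mRNAs without CDS are dropped; features
    whose ``Parent`` cannot be resolved are skipped with a warning; genes
    whose transcripts sit on multiple sequences or mixed strands, or that
    end up with no valid transcript, are excluded (and logged).  With
    ``cds_as_exons`` the CDS intervals double as exons, supporting
    annotations that omit exon rows.
    """
    db = _as_db(source)
    ids = set()
    for ftype in db.featuretypes():
        for feat in db.features_of_type(ftype):
            ids.add(feat.id)
    # orphan check: child features whose Parent is absent
    for ftype in ("mRNA", "exon", "CDS"):
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            continue
        for feat in feats:
            for parent_id in feat.attributes.get("Parent", []):
                if parent_id not in ids:
                    logger.warning(
                        "%s feature %s: unresolvable Parent=%s; skipped",
                        ftype, feat.id, parent_id,
                    )

    genes: list[Gene] = []
    n_excluded = 0
    for gfeat in db.features_of_type("gene"):
        transcripts = []
        for mrna in db.children(gfeat, level=1, featuretype=("mRNA", "transcript")):
            cds = [
                (c.start, c.end)
                for c in db.children(mrna, level=1, featuretype="CDS")
            ]
            if not cds:
                logger.warning("mRNA %s has no CDS; dropped", mrna.id)
                continue
            if cds_as_exons:
                exons = list(cds)
            else:
                exons = [
                    (e.start, e.end)
                    for e in db.children(mrna, level=1, featuretype="exon")
                ]
            if not exons:
                logger.warning("mRNA %s has no exons; dropped", mrna.id)
                continue
            transcripts.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    gene_id=gfeat.id,
                    seq_id=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                )
            )
        if not transcripts:
            n_excluded += 1
            logger.warning("gene %s has no valid mRNA; excluded", gfeat.id)
            continue
        seqs = {t.seq_id for t in transcripts}
        strands = {t.strand for t in transcripts}
        if len(seqs) > 1 or len(strands) > 1:
            n_excluded += 1
            logger.warning(
                "gene %s spans multiple sequences/strands; excluded", gfeat.id
            )
            continue
        genes.append(Gene(gene_id=gfeat.id, transcripts=transcripts))
    if n_excluded:
        logger.info("%d genes excluded during parsing", n_excluded)
    return genes


def genome_size_from_headers(source) -> int:
    """Assembly size in bp: sum of ``##sequence-region`` extents."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and os.path.exists(text):
            with open(text) as handle:
                text = handle.read()
    regions: dict[str, int] = {}
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed directive: {line!r}")
            seqid, start, end = parts[1], int(parts[2]), int(parts[3])
            if seqid in regions:
                raise ValueError(
                    f"duplicated ##sequence-region for {seqid!r}: ambiguous assembly"
                )
            regions[seqid] = end - start + 1
    if not regions:
        raise ValueError(
            "no ##sequence-region directives found; pass the genome size explicitly"
        )
    return sum(regions.values())


# ------------------------------------------------------------- per gene


def select_canonical(gene: Gene) -> TranscriptModel:
    """The transcript with maximal total CDS length.

    Ties break on the lexicographically smallest transcript id, so the
    choice never depends on file order.
    """
    with_cds = [t for t in gene.transcripts if t.cds]
    if not with_cds:
        raise ValueError(f"gene {gene.gene_id} has no transcript with CDS")
    return min(with_cds, key=lambda t: (-t.total_cds_len(), t.transcript_id))


def trim_to_cds(transcript: TranscriptModel) -> TranscriptModel:
    """Clip the exon chain to the CDS span (UTR exons removed or clipped)."""
    if not transcript.cds:
        raise ValueError(f"{transcript.transcript_id}: no CDS to trim to")
    span_start = min(a for a, _ in transcript.cds)
    span_end = max(b for _, b in transcript.cds)
    exons = []
    for a, b in transcript.exons:
        if b < span_start or a > span_end:
            continue
        exons.append((max(a, span_start), min(b, span_end)))
    return replace(transcript, exons=exons)


def infer_introns(transcript: TranscriptModel) -> list[Interval]:
    """Gaps between consecutive exons, 1-based inclusive."""
    introns = []
    for (_, prev_end), (next_start, _) in zip(
        transcript.exons, transcript.exons[1:]
    ):
        if next_start - prev_end - 1 <= 0:
            logger.warning(
                "%s: adjacent exons with zero gap (annotation artifact)",
                transcript.transcript_id,
            )
            continue
        introns.append((prev_end + 1, next_start - 1))
    return introns


def compute_gene_record(transcript: TranscriptModel) -> GeneRecord:
    """Features of a trimmed transcript (call :func:`trim_to_cds` first)."""
    introns = infer_introns(transcript)
    intron_lengths = [b - a + 1 for a, b in introns]
    total_intron = sum(intron_lengths)
    total_exon = sum(b - a + 1 for a, b in transcript.exons)
    if total_exon < 1:
        raise ValueError(f"{transcript.transcript_id}: empty exon set after trim")
    return GeneRecord(
        gene_id=transcript.gene_id,
        transcript_id=transcript.transcript_id,
        n_introns=len(intron_lengths),
        intron_lengths=intron_lengths,
        total_intron_len=total_intron,
        total_exon_len=total_exon,
        intron_ratio=total_intron / total_exon,
        intronless=not intron_lengths,
    )


# ------------------------------------------------------------ per species


def summarize_species(
    records: Sequence[GeneRecord], genome_size: float, species_id: str = "species"
) -> SpeciesSummary:
    """Genome-wide means over all genes (intronless genes included)."""
    if not records:
        raise ValueError("no gene records to summarize")
    n = len(records)
    pooled = [l for r in records for l in r.intron_lengths]
    if pooled:
        mean_intron_len = float(np.mean(pooled))
    else:
        mean_intron_len = math.nan
        logger.warning("%s: no introns genome-wide; mean intron length missing",
                       species_id)
    summary = SpeciesSummary(
        species_id=species_id,
        n_genes=n,
        mean_intron_ratio=float(np.mean([r.intron_ratio for r in records])),
        mean_intron_len=mean_intron_len,
        mean_n_introns=float(np.mean([r.n_introns for r in records])),
        mean_total_intron_len=float(np.mean([r.total_intron_len for r in records])),
        mean_total_exon_len=float(np.mean([r.total_exon_len for r in records])),
        fraction_intronless=sum(r.intronless for r in records) / n,
        genome_size=float(genome_size),
    )
    for name in _LOG10_FIELDS:
        val = getattr(summary, name)
        summary.log10[name] = math.log10(val) if val and val > 0 else math.nan
    return summary


def feature_distribution(
    records: Sequence[GeneRecord],
    feature: str,
    include_intronless: bool = True,
) -> np.ndarray:
    """Genome-wide observation vector for a feature.

    ``intron_ratio`` and ``n_introns`` are per gene; ``intron_length`` pools
    every individual intron in the genome (``intron_length_gene_mean`` is
    the per-gene mean alternative).  ``include_intronless=False`` drops
    intronless genes from the per-gene features (the pooled intron-length
    set is unaffected — intronless genes contribute none).
    """
    if feature == "intron_length":
        vals = [l for r in records for l in r.intron_lengths]
    elif feature == "intron_length_gene_mean":
        vals = [
            r.total_intron_len / r.n_introns for r in records if r.n_introns
        ]
    elif feature in ("intron_ratio", "n_introns"):
        kept = records if include_intronless else [r for r in records if not r.intronless]
        attr = "intron_ratio" if feature == "intron_ratio" else "n_introns"
        vals = [getattr(r, attr) for r in kept]
    else:
        raise ValueError(f"unknown feature {feature!r}")
    return np.asarray(vals, dtype=float)


def extract_species(
    source,
    species_id: str = "species",
    genome_size: float | None = None,
    cds_as_exons: bool = False,
) -> tuple[list[GeneRecord], SpeciesSummary]:
    """Full extraction for one genome: parse → canonical → trim → features."""
    if hasattr(source, "read"):
        source = source.read()
    if genome_size is None:
        genome_size = genome_size_from_headers(source)
    genes = parse_annotations(source, cds_as_exons=cds_as_exons)
    records = []
    for gene in genes:
        canonical = trim_to_cds(select_canonical(gene))
        records.append(compute_gene_record(canonical))
    return records, summarize_species(records, genome_size, species_id)


def records_to_frame(records: Sequence[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "transcript_id": [r.transcript_id for r in records],
            "n_introns": [r.n_introns for r in records],
            "total_intron_len": [r.total_intron_len for r in records],
            "total_exon_len": [r.total_exon_len for r in records],
            "intron_ratio": [r.intron_ratio for r in records],
        }
    )


def write_gff3(
    transcripts: Sequence[TranscriptModel],
    sequence_regions: Mapping[str, int] | None = None,
    dest=None,
) -> str:
    """Serialize transcript models back to GFF3 (gene/mRNA/exon/CDS rows)."""
    lines = ["##gff-version 3"]
    if sequence_regions:
        for seqid, length in sequence_regions.items():
            lines.append(f"##sequence-region {seqid} 1 {length}")
    for tx in transcripts:
        start = min(a for a, _ in tx.exons)
        end = max(b for _, b in tx.exons)
        attrs = f"ID={tx.gene_id}"
        lines.append(
            f"{tx.seq_id}\tgenarch\tgene\t{start}\t{end}\t.\t{tx.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{tx.seq_id}\tgenarch\tmRNA\t{start}\t{end}\t.\t{tx.strand}\t.\t"
            f"ID={tx.transcript_id};Parent={tx.gene_id}"
        )
        for i, (a, b) in enumerate(tx.exons, 1):
            lines.append(
                f"{tx.seq_id}\tgenarch\texon\t{a}\t{b}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}"
            )
        for i, (a, b) in enumerate(tx.cds, 1):
            lines.append(
                f"{tx.seq_id}\tgenarch\tCDS\t{a}\t{b}\t.\t{tx.strand}\t0\t"
                f"ID={tx.transcript_id}.cds{i};Parent={tx.transcript_id}"
            )
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as handle:
                handle.write(text)
    return text
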