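"""Hand-crafted GFF3 fixtures with hand-computed expected gene records.

Each case is (name, gff3 text, expected dict per gene) where the expected
values were worked out by hand from the extraction rules: canonical =
maximal total CDS (ties to the lexicographically smallest transcript id),
exons clipped to the CDS span, introns = inter-exon gaps, intron ratio =
total intron length / total exon length.
"""

HEADER = "##gff-version 3\n##sequence-region chr1 1 100000\n"


def _rows(*rows):
    return HEADER + "\n".join("\t".join(map(str, r)) for r in rows) + "\n"


def g(seq, ftype, start, end, strand, attrs):
    return (seq, "test", ftype, start, end, ".", strand, ".", attrs)


CASES = []

# 1. two coding exons, one intron: exon 200 bp total, intron 100 bp
CASES.append((
    "two_exon_basic",
    _rows(
        g("chr1", "gene", 1, 300, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 300, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 100, "+", "Parent=t1"),
        g("chr1", "exon", 201, 300, "+", "Parent=t1"),
        g("chr1", "CDS", 1, 100, "+", "ID=c1;Parent=t1"),
        g("chr1", "CDS", 201, 300, "+", "ID=c1b;Parent=t1"),
    ),
    {"g1": dict(transcript_id="t1", n_introns=1, total_exon_len=200,
                total_intron_len=100, intron_ratio=0.5, intronless=False)},
))

# 2. single exon, intronless
CASES.append((
    "single_exon",
    _rows(
        g("chr1", "gene", 1, 300, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 300, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 300, "+", "Parent=t1"),
        g("chr1", "CDS", 1, 300, "+", "ID=c1;Parent=t1"),
    ),
    {"g1": dict(transcript_id="t1", n_introns=0, total_exon_len=300,
                total_intron_len=0, intron_ratio=0.0, intronless=True)},
))

# 3. UTR trimming: exons (1-100),(201-300),(401-500); CDS (250-300),(401-450)
#    span = [250,450]: first exon dropped, second clipped to (250,300),
#    third clipped to (401,450); intron (301,400) length 100; exon total 101
CASES.append((
    "utr_trim_clip",
    _rows(
        g("chr1", "gene", 1, 500, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 500, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 100, "+", "Parent=t1"),
        g("chr1", "exon", 201, 300, "+", "Parent=t1"),
        g("chr1", "exon", 401, 500, "+", "Parent=t1"),
        g("chr1", "CDS", 250, 300, "+", "ID=c1;Parent=t1"),
        g("chr1", "CDS", 401, 450, "+", "ID=c2;Parent=t1"),
    ),
    {"g1": dict(transcript_id="t1", n_introns=1, total_exon_len=101,
                total_intron_len=100, intron_ratio=100 / 101, intronless=False)},
))

# 4. single long exon with interior CDS: exon (1,500), CDS (100,400)
CASES.append((
    "interior_cds",
    _rows(
        g("chr1", "gene", 1, 500, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 500, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 500, "+", "Parent=t1"),
        g("chr1", "CDS", 100, 400, "+", "ID=c1;Parent=t1"),
    ),
    {"g1": dict(transcript_id="t1", n_introns=0, total_exon_len=301,
                total_intron_len=0, intron_ratio=0.0, intronless=True)},
))

# 5. canonical selection: t2 has larger total CDS (300 vs 150)
CASES.append((
    "canonical_max_cds",
    _rows(
        g("chr1", "gene", 1, 1000, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 400, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 150, "+", "Parent=t1"),
        g("chr1", "CDS", 1, 150, "+", "ID=c1;Parent=t1"),
        g("chr1", "mRNA", 1, 1000, "+", "ID=t2;Parent=g1"),
        g("chr1", "exon", 1, 150, "+", "Parent=t2"),
        g("chr1", "exon", 851, 1000, "+", "Parent=t2"),
        g("chr1", "CDS", 1, 150, "+", "ID=c2;Parent=t2"),
        g("chr1", "CDS", 851, 1000, "+", "ID=c2b;Parent=t2"),
    ),
    {"g1": dict(transcript_id="t2", n_introns=1, total_exon_len=300,
                total_intron_len=700, intron_ratio=700 / 300, intronless=False)},
))

# 6. canonical tie (200 vs 200): lexicographically smallest id wins (ta < tb)
CASES.append((
    "canonical_tie",
    _rows(
        g("chr1", "gene", 1, 1000, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 500, "+", "ID=tb;Parent=g1"),
        g("chr1", "exon", 1, 100, "+", "Parent=tb"),
        g("chr1", "exon", 401, 500, "+", "Parent=tb"),
        g("chr1", "CDS", 1, 100, "+", "ID=cb;Parent=tb"),
        g("chr1", "CDS", 401, 500, "+", "ID=cb2;Parent=tb"),
        g("chr1", "mRNA", 1, 200, "+", "ID=ta;Parent=g1"),
        g("chr1", "exon", 1, 200, "+", "Parent=ta"),
        g("chr1", "CDS", 1, 200, "+", "ID=ca;Parent=ta"),
    ),
    {"g1": dict(transcript_id="ta", n_introns=0, total_exon_len=200,
                total_intron_len=0, intron_ratio=0.0, intronless=True)},
))

# 7. reverse strand: mirrored coordinates, same feature values as case 1
CASES.append((
    "reverse_strand",
    _rows(
        g("chr1", "gene", 701, 1000, "-", "ID=g1"),
        g("chr1", "mRNA", 701, 1000, "-", "ID=t1;Parent=g1"),
        g("chr1", "exon", 701, 800, "-", "Parent=t1"),
        g("chr1", "exon", 901, 1000, "-", "Parent=t1"),
        g("chr1", "CDS", 701, 800, "-", "ID=c1;Parent=t1"),
        g("chr1", "CDS", 901, 1000, "-", "ID=c1b;Parent=t1"),
    ),
    {"g1": dict(transcript_id="t1", n_introns=1, total_exon_len=200,
                total_intron_len=100, intron_ratio=0.5, intronless=False)},
))

# 8. tiny introns: exons (1,10),(12,20),(40,50) → intron lengths 1 and 19
CASES.append((
    "tiny_introns",
    _rows(
        g("chr1", "gene", 1, 50, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 50, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 10, "+", "Parent=t1"),
        g("chr1", "exon", 12, 20, "+", "Parent=t1"),
        g("chr1", "exon", 40, 50, "+", "Parent=t1"),
        g("chr1", "CDS", 1, 10, "+", "ID=c1;Parent=t1"),
        g("chr1", "CDS", 12, 20, "+", "ID=c2;Parent=t1"),
        g("chr1", "CDS", 40, 50, "+", "ID=c3;Parent=t1"),
    ),
    # exon lengths 10 + 9 + 11 = 30; introns (11,11)=1 and (21,39)=19
    {"g1": dict(transcript_id="t1", n_introns=2, total_exon_len=30,
                total_intron_len=20, intron_ratio=20 / 30, intronless=False)},
))

# 9. adjacent exons with zero gap: no intron emitted between (1,100),(101,200)
CASES.append((
    "zero_gap_exons",
    _rows(
        g("chr1", "gene", 1, 400, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 400, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 100, "+", "Parent=t1"),
        g("chr1", "exon", 101, 200, "+", "Parent=t1"),
        g("chr1", "exon", 301, 400, "+", "Parent=t1"),
        g("chr1", "CDS", 1, 100, "+", "ID=c1;Parent=t1"),
        g("chr1", "CDS", 101, 200, "+", "ID=c2;Parent=t1"),
        g("chr1", "CDS", 301, 400, "+", "ID=c3;Parent=t1"),
    ),
    {"g1": dict(transcript_id="t1", n_introns=1, total_exon_len=300,
                total_intron_len=100, intron_ratio=100 / 300, intronless=False)},
))

# 10. two genes, one of them with a CDS-less mRNA that must be ignored
CASES.append((
    "mixed_two_genes",
    _rows(
        g("chr1", "gene", 1, 300, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 300, "+", "ID=g1t1;Parent=g1"),
        g("chr1", "exon", 1, 100, "+", "Parent=g1t1"),
        g("chr1", "exon", 201, 300, "+", "Parent=g1t1"),
        g("chr1", "CDS", 1, 100, "+", "ID=g1c;Parent=g1t1"),
        g("chr1", "CDS", 201, 300, "+", "ID=g1c2;Parent=g1t1"),
        g("chr1", "gene", 1001, 1600, "+", "ID=g2"),
        g("chr1", "mRNA", 1001, 1300, "+", "ID=g2t1;Parent=g2"),
        g("chr1", "exon", 1001, 1300, "+", "Parent=g2t1"),
        g("chr1", "mRNA", 1001, 1600, "+", "ID=g2t2;Parent=g2"),
        g("chr1", "exon", 1001, 1100, "+", "Parent=g2t2"),
        g("chr1", "exon", 1401, 1600, "+", "Parent=g2t2"),
        g("chr1", "CDS", 1001, 1100, "+", "ID=g2c;Parent=g2t2"),
        g("chr1", "CDS", 1401, 1600, "+", "ID=g2c2;Parent=g2t2"),
    ),
    {"g1": dict(transcript_id="g1t1", n_introns=1, total_exon_len=200,
                total_intron_len=100, intron_ratio=0.5, intronless=False),
     "g2": dict(transcript_id="g2t2", n_introns=1, total_exon_len=300,
                total_intron_len=300, intron_ratio=1.0, intronless=False)},
))

# 11. UTR exon entirely upstream of the CDS span must disappear
CASES.append((
    "detached_utr_exon",
    _rows(
        g("chr1", "gene", 1, 900, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 900, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 100, "+", "Parent=t1"),
        g("chr1", "exon", 301, 500, "+", "Parent=t1"),
        g("chr1", "exon", 701, 900, "+", "Parent=t1"),
        g("chr1", "CDS", 350, 500, "+", "ID=c1;Parent=t1"),
        g("chr1", "CDS", 701, 800, "+", "ID=c2;Parent=t1"),
    ),
    # span [350,800]: exon1 gone, exon2 → (350,500), exon3 → (701,800);
    # intron (501,700) length 200; exon total 151 + 100 = 251
    {"g1": dict(transcript_id="t1", n_introns=1, total_exon_len=251,
                total_intron_len=200, intron_ratio=200 / 251, intronless=False)},
))

# 12. three exons, two introns of different sizes
CASES.append((
    "three_exon",
    _rows(
        g("chr1", "gene", 1, 1000, "+", "ID=g1"),
        g("chr1", "mRNA", 1, 1000, "+", "ID=t1;Parent=g1"),
        g("chr1", "exon", 1, 100, "+", "Parent=t1"),
        g("chr1", "exon", 201, 400, "+", "Parent=t1"),
        g("chr1", "exon", 901, 1000, "+", "Parent=t1"),
        g("chr1", "CDS", 1, 100, "+", "ID=c1;Parent=t1"),
        g("chr1", "CDS", 201, 400, "+", "ID=c2;Parent=t1"),
        g("chr1", "CDS", 901, 1000, "+", "ID=c3;Parent=t1"),
    ),
    # introns (101,200)=100 and (401,900)=500; exons 100+200+100=400
    {"g1": dict(transcript_id="t1", n_introns=2, total_exon_len=400,
                total_intron_len=600, intron_ratio=1.5, intronless=False)},
))
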