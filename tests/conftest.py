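import pytest

from tecre.intervals import GenomicInterval, Peak, TEInstance

GENOME = [("chr1", 5_000_000), ("chr2", 5_000_000)]


@pytest.fixture(scope="session")
def genome():
    return GENOME


@pytest.fixture(scope="session")
def te_annotation():
    """30 families x 100 copies on a 10 Mb toy genome (shared, read-only)."""
    from tecre.simulate import simulate_te_annotation

    instances, seqs, registry = simulate_te_annotation(GENOME, 30, 100, seed=101)
    return instances, seqs, registry


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=200):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(str(rng.choice(chroms)), start, start + length)
        )
    return out


def brute_force_overlap(a, b, min_fraction_of_a=0.0):
    """O(n*m) all-vs-all oracle for overlap_join."""
    from tecre.intervals import as_interval

    pairs = []
    for i, ra in enumerate(a):
        ia = as_interval(ra)
        for j, rb in enumerate(b):
            ib = as_interval(rb)
            ov = ia.overlap_bp(ib)
            if ov >= 1 and ov / len(ia) >= min_fraction_of_a:
                pairs.append((i, j, ov))
    return pairs


def brute_force_closest(query, targets):
    """Exhaustive nearest-anchor oracle for closest_distance."""
    from tecre.intervals import as_interval

    out = []
    for i, rec in enumerate(query):
        iv = as_interval(rec)
        best = None
        for tid, chrom, pos in targets:
            if chrom != iv.chrom:
                continue
            if iv.start <= pos <= iv.end:
                d = 0
            elif pos < iv.start:
                d = iv.start - pos
            else:
                d = pos - iv.end
            key = (d, pos, tid)
            if best is None or key < best:
                best = key
        if best is not None:
            out.append((i, best[2], best[0]))
    return out


def make_te(chrom, start, end, family, iid, strand="+"):
    return TEInstance(
        interval=GenomicInterval(chrom, start, end, strand), family=family, id=iid
    )


def make_peak(chrom, start, end, dataset="d1", signal=1.0):
    return Peak(
        interval=GenomicInterval(chrom, start, end), signal=signal, dataset=dataset
    )
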