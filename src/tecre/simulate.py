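"""Seeded synthetic fixtures with the statistical structure each stage assumes.

Every generator is a pure function of (config, seed) and emits a truth record
alongside its fixture, so downstream recovery tests never re-derive ground
truth. One global integer seed expands to per-stage child seeds by the fixed
offsets in ``STAGE_OFFSETS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .intervals import GeneModel, GenomicInterval, Peak, TEInstance, TranscriptModel

BASES = np.array(list("ACGT"))

STAGE_OFFSETS = {
    "te": 11,
    "peaks": 23,
    "polya": 37,
    "expression": 41,
    "cnv": 53,
    "genes": 67,
}


def child_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage child seed, kept below 2**31."""
    return (seed * 1_000_003 + STAGE_OFFSETS[stage] * 8191 + index) % (2**31)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


# ---------------------------------------------------------------------------
# TE annotation
# ---------------------------------------------------------------------------

def simulate_te_annotation(
    genome: Sequence[tuple[str, int]],
    families: Union[int, Sequence[str]],
    instances_per_family: Union[int, dict[str, int]],
    seed: int,
    length_range: tuple[int, int] = (150, 450),
) -> tuple[list[TEInstance], dict[str, str], list[str]]:
    """Place non-overlapping repeat copies of many families on a toy genome.

    Returns (instances, instance sequences, family registry). Families with a
    count of 0 stay in the registry but are absent from the output. Instances
    are placed uniformly at random without overlap within each chromosome
    (sorted-gap construction); strands are uniform. Raises when the requested
    repeat space exceeds 50% of the genome.
    """
    rng = np.random.default_rng(seed)
    if isinstance(families, int):
        families = [f"FAM{i:03d}" for i in range(families)]
    registry = list(families)
    if isinstance(instances_per_family, int):
        counts = {f: instances_per_family for f in registry}
    else:
        counts = {f: int(instances_per_family.get(f, 0)) for f in registry}
    labels = [f for f in registry for _ in range(counts[f])]
    n = len(labels)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
    genome_bp = sum(length for _, length in genome)
    need = int(lengths.sum())
    if need > genome_bp // 2:
        raise ValueError(
            f"genome too small: placing {need} bp of repeats needs a genome "
            f"of at least {2 * need} bp"
        )
    # Assign instances to chromosomes proportionally to length, then place
    # each chromosome's set via sorted uniform gaps (uniform non-overlapping).
    order = rng.permutation(n)
    probs = np.array([length for _, length in genome], dtype=float)
    probs /= probs.sum()
    chrom_of = rng.choice(len(genome), size=n, p=probs)
    instances: list[TEInstance] = []
    seqs: dict[str, str] = {}
    per_family_counter: dict[str, int] = {f: 0 for f in registry}
    for ci, (chrom, clen) in enumerate(genome):
        idx = order[chrom_of[order] == ci]
        if idx.size == 0:
            continue
        lens = lengths[idx]
        free = clen - int(lens.sum())
        if free < 0:
            raise ValueError(
                f"chromosome {chrom} too small for {int(lens.sum())} bp of repeats"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=idx.size))
        starts = gaps + np.concatenate(([0], np.cumsum(lens[:-1])))
        for k, inst_i in enumerate(idx):
            fam = labels[inst_i]
            iid = f"{fam}.{per_family_counter[fam]}"
            per_family_counter[fam] += 1
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, int(starts[k]), int(starts[k] + lens[k]), strand)
            instances.append(
                TEInstance(
                    interval=iv,
                    family=fam,
                    id=iid,
                    divergence=float(np.round(rng.uniform(0, 25), 2)),
                )
            )
            seqs[iid] = _random_seq(rng, len(iv))
    instances.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return instances, seqs, registry


# ---------------------------------------------------------------------------
# Peak sets with planted per-family enrichment
# ---------------------------------------------------------------------------

def simulate_peakset(
    te_instances: Sequence[TEInstance],
    genome: Sequence[tuple[str, int]],
    dataset_name: str,
    n_peaks: int,
    enrichment_spec: Optional[dict[str, float]] = None,
    seed: int = 0,
    mean_width: int = 300,
) -> list[Peak]:
    """Background peaks uniform over the genome; enriched families get their
    footprint's placement probability multiplied by the stated fold.

    The expected fraction of a family's instances overlapped by >= 1 peak is
    monotone increasing in its fold; an empty fold map is the uniform null.
    """
    enrichment_spec = dict(enrichment_spec or {})
    fams = {t.family for t in te_instances}
    for fam, fold in enrichment_spec.items():
        if fam not in fams:
            raise ValueError(f"enrichment fold given for unknown family {fam!r}")
        if fold < 1:
            raise ValueError(f"fold for family {fam!r} must be >= 1, got {fold}")
    rng = np.random.default_rng(seed)
    chroms = [c for c, _ in genome]
    clens = np.array([length for _, length in genome], dtype=float)
    genome_bp = clens.sum()
    by_family: dict[str, list[TEInstance]] = {}
    for t in te_instances:
        by_family.setdefault(t.family, []).append(t)
    comp_names = ["background"]
    comp_weights = [genome_bp]
    for fam, fold in sorted(enrichment_spec.items()):
        footprint = sum(len(t.interval) for t in by_family[fam])
        comp_names.append(fam)
        comp_weights.append((fold - 1.0) * footprint)
    w = np.array(comp_weights, dtype=float)
    w /= w.sum()
    peaks: list[Peak] = []
    chrom_p = clens / genome_bp
    for _ in range(n_peaks):
        width = max(50, int(round(rng.normal(mean_width, mean_width / 4))))
        comp = rng.choice(len(comp_names), p=w)
        if comp == 0:
            ci = rng.choice(len(chroms), p=chrom_p)
            chrom, clen = chroms[ci], int(clens[ci])
            center = int(rng.integers(0, clen))
        else:
            insts = by_family[comp_names[comp]]
            fw = np.array([len(t.interval) for t in insts], dtype=float)
            inst = insts[rng.choice(len(insts), p=fw / fw.sum())]
            chrom = inst.interval.chrom
            clen = int(clens[chroms.index(chrom)])
            center = int(rng.integers(inst.interval.start, inst.interval.end))
        start = max(0, center - width // 2)
        end = min(clen, start + width)
        if end <= start:
            continue
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end, "."),
                signal=float(rng.exponential(10.0)),
                dataset=dataset_name,
            )
        )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


# ---------------------------------------------------------------------------
# PolyA windows diverged from a family consensus
# ---------------------------------------------------------------------------

def _scrub_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Remove every occurrence of motif by a minimal (1-bp) substitution."""
    seq = list(seq)
    mlen = len(motif)
    i = 0
    while i <= len(seq) - mlen:
        if "".join(seq[i : i + mlen]) == motif:
            mid = i + mlen // 2
            choices = [b for b in "ACGT" if b != seq[mid]]
            seq[mid] = choices[int(rng.integers(0, 3))]
            i = max(0, i - mlen + 1)
        else:
            i += 1
    return "".join(seq)


def simulate_polya_instances(
    n_instances: int,
    divergence: float,
    plant_rate: float,
    hexamer_pos: int,
    seed: int,
    consensus_seq: Optional[str] = None,
    consensus_length: int = 600,
    window: int = 200,
    motif: str = "AATAAA",
) -> tuple[str, dict[str, str], pd.DataFrame]:
    """Instance windows diverged from a motif-free consensus, with the polyA
    hexamer planted at a fixed consensus position in a random subset.

    Each instance is a ``window``-nt slice of the consensus (random offset,
    always covering ``hexamer_pos``) with i.i.d. substitutions at the
    divergence rate; with probability ``plant_rate`` the exact motif is then
    written at the consensus-coordinate plant position. The consensus itself
    is scrubbed of the motif by minimal substitutions. Returns
    (consensus, {instance_id: sequence}, truth table).
    """
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must lie in [0, 1]")
    if not 0 <= divergence < 1:
        raise ValueError("divergence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if consensus_seq is None:
        consensus_seq = _random_seq(rng, consensus_length)
    if len(consensus_seq) < window:
        raise ValueError(f"consensus must be >= {window} nt")
    if hexamer_pos + len(motif) > len(consensus_seq):
        raise ValueError("hexamer position does not fit in the consensus")
    consensus_seq = _scrub_motif(consensus_seq.upper(), motif, rng)
    off_lo = max(0, hexamer_pos + len(motif) - window)
    off_hi = min(len(consensus_seq) - window, hexamer_pos)
    if off_lo > off_hi:
        raise ValueError("plant position collides with the window layout")
    seqs: dict[str, str] = {}
    rows = []
    for i in range(n_instances):
        offset = int(rng.integers(off_lo, off_hi + 1))
        inst = np.array(list(consensus_seq[offset : offset + window]))
        if divergence > 0:
            hit = rng.random(window) < divergence
            for j in np.flatnonzero(hit):
                inst[j] = rng.choice([b for b in "ACGT" if b != inst[j]])
        planted = bool(rng.random() < plant_rate)
        pos_in_window = hexamer_pos - offset
        if planted:
            inst[pos_in_window : pos_in_window + len(motif)] = list(motif)
        iid = f"inst{i:03d}"
        seqs[iid] = "".join(inst)
        rows.append(
            {
                "instance": iid,
                "consensus_offset": offset,
                "planted": planted,
                "plant_pos_window": pos_in_window,
                "plant_pos_consensus": hexamer_pos,
            }
        )
    return consensus_seq, seqs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression with a planted two-TF additive dosage effect
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int,
    n_samples: int,
    a: float,
    b: float,
    sigma: float,
    seed: int,
    tf1: str = "GATA3",
    tf2: str = "DLX5",
    target: str = "PSG9",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Genes x samples expression with ``target = a*Z(tf1) + b*Z(tf2) + noise``.

    The two TF genes are i.i.d. standard normal per sample on the latent log2
    scale; remaining genes are i.i.d. noise. Returns (log2 matrix, raw matrix
    mimicking TPM via 2**log2, truth record). The pipeline's log2 transform
    of the raw matrix recovers the latent scale exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(n_samples)]

    def standardized(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=1)

    # TF draws are emitted empirically standardized so the pipeline's
    # per-gene Z-scores reproduce them exactly (and the noiseless limit of
    # the combined correlation is exactly 1)
    z1 = standardized(rng.standard_normal(n_samples))
    z2 = standardized(rng.standard_normal(n_samples))
    tgt = a * z1 + b * z2 + rng.normal(0, sigma, n_samples)
    others = rng.standard_normal((max(0, n_genes - 3), n_samples))
    names = [tf1, tf2, target] + [f"G{i:04d}" for i in range(max(0, n_genes - 3))]
    data = np.vstack([z1, z2, tgt, others]) if len(others) else np.vstack([z1, z2, tgt])
    log2 = pd.DataFrame(data, index=names, columns=samples)
    truth = {"tf1": tf1, "tf2": tf2, "target": target, "a": a, "b": b, "sigma": sigma}
    return log2, 2.0**log2, truth


# ---------------------------------------------------------------------------
# CNV / SV tables over a locus window
# ---------------------------------------------------------------------------

def simulate_cnv_table(
    groups: dict[str, dict],
    locus_window: GenomicInterval,
    seed: int,
    size_range: tuple[int, int] = (1000, 20000),
) -> pd.DataFrame:
    """Per-sample loss/gain events in a locus window; counts are Poisson with
    group-specific rates, sizes uniform in ``size_range``.

    ``groups`` maps a group label to ``{"n_samples": int, "loss_rate": float,
    "gain_rate": float}``. Columns: sample, group, chrom, start, end, type,
    size.
    """
    if not groups:
        raise ValueError("need at least one group")
    if size_range[0] < 1:
        raise ValueError("minimum event size must be >= 1")
    rng = np.random.default_rng(seed)
    wlen = len(locus_window)
    rows = []
    for gname in sorted(groups):
        spec = groups[gname]
        for si in range(int(spec["n_samples"])):
            sample = f"{gname}_{si:03d}"
            for etype, rate_key in (("loss", "loss_rate"), ("gain", "gain_rate")):
                k = rng.poisson(float(spec.get(rate_key, 0.0)))
                for _ in range(k):
                    size = int(rng.integers(size_range[0], size_range[1] + 1))
                    size = min(size, wlen)
                    start = locus_window.start + int(rng.integers(0, wlen - size + 1))
                    rows.append(
                        {
                            "sample": sample,
                            "group": gname,
                            "chrom": locus_window.chrom,
                            "start": start,
                            "end": start + size,
                            "type": etype,
                            "size": size,
                        }
                    )
    cols = ["sample", "group", "chrom", "start", "end", "type", "size"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Membrane / secreted isoform pair
# ---------------------------------------------------------------------------

POLAR = list("STNQDEKRGH")
HYDROPHOBIC = list("ILVF")


def simulate_isoform_pair(
    seed: int, core_length: int = 150, tail_length: int = 25
) -> tuple[str, str]:
    """A protein isoform pair sharing a core: the membrane form carries a
    hydrophobic C-terminal tail, the secreted form stops at the shared core.

    Emulates the ancestral membrane-anchored / derived secreted pair produced
    when an alternative polyA site truncates the transmembrane-encoding
    terminal exon. The core is polar overall with a short apolar stretch
    just before the junction, as upstream of a natural transmembrane anchor.
    """
    rng = np.random.default_rng(seed)
    core = "".join(rng.choice(POLAR, size=core_length - 8)) + "A" * 8
    tail = "".join(rng.choice(HYDROPHOBIC, size=tail_length))
    return core + tail, core


# ---------------------------------------------------------------------------
# Gene models with controlled 3'-end / TE architecture
# ---------------------------------------------------------------------------

def simulate_gene_models(
    te_instances: Sequence[TEInstance],
    family: str,
    n_genes: int,
    n_proximal: int,
    seed: int,
    genome: Sequence[tuple[str, int]],
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Two-exon gene models, ``n_proximal`` of which end inside a copy of
    ``family`` (distance 0 to the 3' end) and the rest far (> 2 kb) from any.

    Emulates a gene array whose members do / do not read through a repeat
    copy at their 3' end. Returns (genes, truth table with the planted
    proximal flag).
    """
    rng = np.random.default_rng(seed)
    fam_copies = [t for t in te_instances if t.family == family]
    if n_proximal > min(n_genes, len(fam_copies)):
        raise ValueError("not enough family copies to host the proximal genes")
    chosen = list(rng.choice(len(fam_copies), size=n_proximal, replace=False))
    genes: list[GeneModel] = []
    rows = []
    clen = dict(genome)
    for gi in range(n_genes):
        gid = f"gene{gi:03d}"
        if gi < n_proximal:
            te = fam_copies[chosen[gi]]
            chrom = te.interval.chrom
            end3 = int(rng.integers(te.interval.start + 1, te.interval.end + 1))
            proximal = True
        else:
            chrom, length = genome[int(rng.integers(0, len(genome)))]
            for _ in range(1000):
                end3 = int(rng.integers(5000, length - 5000))
                if all(
                    t.interval.chrom != chrom
                    or min(abs(end3 - t.interval.start), abs(end3 - t.interval.end))
                    > 2500
                    for t in te_instances
                ):
                    break
            else:  # pragma: no cover - pathological genome
                raise ValueError("could not place a distal gene end")
            proximal = False
        start = max(0, end3 - 3000)
        exons = [
            GenomicInterval(chrom, start, start + 800, "+"),
            GenomicInterval(chrom, min(end3 - 900, start + 1000), end3, "+"),
        ]
        tm = TranscriptModel(transcript_id=f"{gid}.t1", exons=exons, polya_site=end3)
        genes.append(GeneModel(gene_id=gid, strand="+", transcripts=[tm]))
        rows.append({"gene": gid, "chrom": chrom, "end3": end3, "proximal": proximal})
    return genes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config-driven fixture generation (CLI surface)
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Bundle of per-stage settings; defaults mirror the study-scale fixture."""

    seed: int = 0
    genome: list = field(default_factory=lambda: [("chr1", 5_000_000), ("chr2", 5_000_000)])
    n_families: int = 30
    instances_per_family: int = 100
    peak_datasets: list = field(
        default_factory=lambda: [
            ("GATA3", 1500, 300),
            ("DLX5", 1500, 300),
            ("TFAP2C", 1500, 300),
            ("H3K4me3", 1500, 500),
        ]
    )
    enrichment_spec: dict = field(default_factory=dict)
    polya_spec: dict = field(
        default_factory=lambda: dict(
            consensus_length=600, n_instances=14, divergence=0.08,
            plant_rate=12 / 14, hexamer_pos=320,
        )
    )
    expression_spec: dict = field(
        default_factory=lambda: dict(n_genes=200, n_samples=18, a=1.0, b=1.0, sigma=1.0)
    )
    cnv_spec: dict = field(
        default_factory=lambda: dict(
            groups={
                "control": dict(n_samples=21, loss_rate=1.0, gain_rate=1.0),
                "case": dict(n_samples=76, loss_rate=1.0, gain_rate=3.0),
            },
            window=("chr19", 40_000_000, 48_000_000),
        )
    )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        cfg.genome = [tuple(g) for g in cfg.genome]
        cfg.peak_datasets = [tuple(p) for p in cfg.peak_datasets]
        return cfg


def generate_fixtures(config: SimulationConfig, outdir) -> dict[str, str]:
    """Write the full fixture set (BED, FASTA, TSV) plus a truth manifest."""
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    seed = config.seed
    te, te_seqs, _ = simulate_te_annotation(
        config.genome, config.n_families, config.instances_per_family,
        seed=child_seed(seed, "te"),
    )
    tio.write_bed(te, outdir / "te_annotation.bed")
    tio.write_fasta(te_seqs, outdir / "te_sequences.fasta")
    manifest["te_annotation"] = "te_annotation.bed"
    for di, (name, n_peaks, width) in enumerate(config.peak_datasets):
        # config.enrichment_spec maps family -> {dataset: fold}
        folds = {
            fam: per_ds[name]
            for fam, per_ds in config.enrichment_spec.items()
            if name in per_ds
        }
        peaks = simulate_peakset(
            te, config.genome, name, n_peaks, enrichment_spec=folds,
            seed=child_seed(seed, "peaks", di), mean_width=width,
        )
        fn = f"peaks_{name}.bed"
        tio.write_bed(peaks, outdir / fn)
        manifest[f"peaks:{name}"] = fn
    ps = config.polya_spec
    cons, windows, truth = simulate_polya_instances(
        n_instances=ps["n_instances"], divergence=ps["divergence"],
        plant_rate=ps["plant_rate"], hexamer_pos=ps["hexamer_pos"],
        seed=child_seed(seed, "polya"), consensus_length=ps["consensus_length"],
    )
    tio.write_fasta({"consensus": cons}, outdir / "consensus.fasta")
    tio.write_fasta(windows, outdir / "polya_windows.fasta")
    truth.to_csv(outdir / "polya_truth.tsv", sep="\t", index=False)
    manifest["polya_truth"] = "polya_truth.tsv"
    es = config.expression_spec
    log2, raw, _ = simulate_expression(seed=child_seed(seed, "expression"), **es)
    log2.to_csv(outdir / "expression_log2.tsv", sep="\t")
    raw.to_csv(outdir / "expression_tpm.tsv", sep="\t")
    manifest["expression"] = "expression_log2.tsv"
    cs = config.cnv_spec
    wchrom, wstart, wend = cs["window"]
    cnv = simulate_cnv_table(
        cs["groups"], GenomicInterval(wchrom, wstart, wend), seed=child_seed(seed, "cnv")
    )
    cnv.to_csv(outdir / "cnv.tsv", sep="\t", index=False)
    manifest["cnv"] = "cnv.tsv"
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest
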