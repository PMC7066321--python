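"""Synthetic genomes and proximity-ligation read sets with planted truth.

The simulator provides ground truth for every downstream stage:

* :func:`make_genome` builds a random genome whose only enzyme-motif
  occurrences sit at a jittered target spacing, so the restriction map is
  known exactly;
* :func:`build_truth` turns a config into per-site capture probabilities —
  a distance-decaying cis background around the bait, a uniform trans
  baseline, and planted enriched regions multiplying either;
* :func:`simulate_4c_reads` emits primer-anchored single-end 4C reads
  (primer + partner fragment end), inflated by geometric PCR duplication;
* :func:`simulate_capturec_reads` emits paired-end Capture-C reads whose
  molecules carry a viewpoint/partner ligation junction at the motif.

Default parameters are the simulated study conditions; see docs/methods.md
for how each default was chosen.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digest import RestrictionMap, digest, find_sites, resolve_enzyme
from .io import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedRegion:
    """An interval whose restriction sites get an enrichment weight >= 1."""

    chrom: str
    start: int
    end: int
    weight: float

    def __post_init__(self):
        if self.weight < 1:
            raise ValueError("planted enrichment weight must be >= 1")
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid planted interval [{self.start}, {self.end})")


def _default_chroms() -> dict[str, int]:
    return {"chr1": 1_000_000, "chr2": 500_000, "chr3": 500_000, "chr4": 500_000}


@dataclass
class SimConfig:
    """Study conditions for a simulated viewpoint experiment.

    Attributes
    ----------
    chrom_lengths : dict
        Chromosome names and lengths in bp. The first chromosome listed in
        ``bait_chrom`` carries the viewpoint.
    spacing : int
        Target inter-site spacing in bp; realized spacings are jittered
        uniformly by +/-25%.
    enzyme : str
        Enzyme name (built-in table) or raw motif.
    bait_chrom, bait_site_index :
        The viewpoint restriction site. ``None`` site index means the middle
        site of the bait chromosome.
    primer_length : int
        4C primer length; the primer is the genomic sequence immediately
        upstream of the bait site.
    alpha : float
        Cis distance-decay exponent: a cis site at distance d (in sites)
        from the bait has raw weight ``(1 + d) ** -alpha``.
    trans_base : float
        Uniform raw weight of every trans site, on the same scale
        (the zero-distance cis weight is 1).
    planted : list of PlantedRegion
        Enrichment multipliers applied on top of the background mixture.
    n_molecules : int
        Number of unique captured molecules (reads before PCR duplication).
    duplication_rate : float
        PCR duplication rate in [0, 1); each molecule is emitted
        ``Geometric(1 - rate)`` times (rate 0 -> exactly once).
    read_length : int
        4C read length; must cover primer + capture end.
    capture_end_length : int
        Length of the partner fragment end carried by a 4C read.
    cc_read_length : int
        Capture-C mate length (125 bp paired-end by default).
    overlap_fraction : float
        Fraction of Capture-C molecules short enough for the mates to
        overlap centrally (and thus be merge-reconstructable).
    substitution_rate : float
        Optional uniform base-call error rate (off by default).
    seed : int
        Master seed; all random streams derive from it.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    spacing: int = 1000
    enzyme: str = "HindIII"
    bait_chrom: str = "chr1"
    bait_site_index: int | None = None
    primer_length: int = 25
    alpha: float = 2.0
    trans_base: float = 1e-5
    planted: list[PlantedRegion] = field(default_factory=list)
    n_molecules: int = 50_000
    duplication_rate: float = 0.0
    read_length: int = 65
    capture_end_length: int = 40
    cc_read_length: int = 125
    overlap_fraction: float = 1.0
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.duplication_rate < 1:
            raise ValueError("duplication_rate must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.trans_base <= 0:
            raise ValueError("trans_base must be > 0")
        if not 20 <= self.primer_length <= 25:
            raise ValueError("primer_length must be in [20, 25]")
        if self.read_length < self.primer_length + self.capture_end_length:
            raise ValueError("read_length must cover primer + capture end")
        for region in self.planted:
            if region.chrom not in self.chrom_lengths:
                raise ValueError(f"planted region on unknown chromosome {region.chrom}")
            if region.end > self.chrom_lengths[region.chrom]:
                raise ValueError("planted region outside chromosome bounds")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # Independent, seed-deterministic streams: genome=0, partners=1,
    # duplication=2, shear=3, overlap=4, errors=5. Keeping duplication on
    # its own stream makes molecule draws invariant to the duplication rate.
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _find_occurrences(arr: np.ndarray, motif: np.ndarray) -> np.ndarray:
    m = len(motif)
    n = len(arr) - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    match = arr[:n] == motif[0]
    for j in range(1, m):
        match &= arr[j : n + j] == motif[j]
    return np.nonzero(match)[0].astype(np.int64)


def make_genome(config: SimConfig):
    """Build a synthetic genome with motifs planted at jittered spacing.

    Returns ``(genome, rmap, planted_sites)`` where ``planted_sites`` maps
    each chromosome to its planted motif start positions. The background
    sequence is patched so that no spurious motif occurrence survives:
    ``digest`` finds sites exactly where planted. Byte-identical output for
    identical configs (seed determinism).
    """
    enzyme = resolve_enzyme(config.enzyme)
    motif = np.frombuffer(enzyme.motif.encode(), dtype=np.uint8)
    m = len(motif)
    if config.spacing <= m:
        raise ValueError(f"spacing ({config.spacing}) must exceed motif length ({m})")
    rng = _rng(config, 0)
    lo, hi = 0.75 * config.spacing, 1.25 * config.spacing
    genome: dict[str, str] = {}
    planted: dict[str, np.ndarray] = {}
    for chrom, L in config.chrom_lengths.items():
        arr = _BASES[rng.integers(0, 4, size=L)]
        positions = []
        p = int(round(rng.uniform(lo, hi)))
        while p + m <= L:
            positions.append(p)
            p += max(m + 1, int(round(rng.uniform(lo, hi))))
        sites = np.asarray(positions, dtype=np.int64)
        for q in positions:
            arr[q : q + m] = motif
        # Remove spurious occurrences by mutating one base per occurrence,
        # never touching a planted motif window; repeat until clean.
        for _ in range(100):
            occ = _find_occurrences(arr, motif)
            spurious = np.setdiff1d(occ, sites)
            if spurious.size == 0:
                break
            for p0 in spurious.tolist():
                offsets = np.arange(p0, p0 + m)
                if sites.size:
                    j = np.searchsorted(sites, p0, side="right")
                    protected = np.zeros(m, dtype=bool)
                    for q in sites[max(0, j - 1) : j + 1].tolist():
                        protected |= (offsets >= q) & (offsets < q + m)
                    free = offsets[~protected]
                else:
                    free = offsets
                o = int(free[rng.integers(0, len(free))])
                choices = _BASES[_BASES != arr[o]]
                arr[o] = choices[rng.integers(0, len(choices))]
        else:  # pragma: no cover - patching always converges in practice
            raise RuntimeError(f"could not remove spurious motifs on {chrom}")
        genome[chrom] = arr.tobytes().decode("ascii")
        planted[chrom] = sites
    rmap = digest(genome, enzyme)
    return genome, rmap, planted


@dataclass
class SimTruth:
    """Planted interaction structure and the generator's own draw log."""

    bait: tuple[str, int]
    planted: list[PlantedRegion]
    chroms: list[str]
    probs: dict[str, np.ndarray]  # per-site capture probability, bait = 0
    offsets: dict[str, int]  # chrom -> offset into the flat probability vector
    flat_probs: np.ndarray
    draw_counts: dict[str, np.ndarray] | None = None  # filled by simulate_4c_reads
    molecules: list | None = None  # filled by simulate_capturec_reads
    n_molecules: int = 0

    def site_of(self, gidx: int) -> tuple[str, int]:
        """Map a flat site index back to ``(chrom, site index)``."""
        for chrom in reversed(self.chroms):
            if gidx >= self.offsets[chrom]:
                return chrom, gidx - self.offsets[chrom]
        raise IndexError(gidx)


def build_truth(rmap: RestrictionMap, config: SimConfig) -> SimTruth:
    """Per-site capture probabilities for the configured mixture.

    Cis weight is ``(1 + d)^-alpha`` (d = site distance to the bait, in
    sites); trans weight is the uniform ``trans_base``; sites inside a
    planted region have their weight multiplied by the region's enrichment.
    The bait site itself has probability 0. Probabilities sum to 1.
    """
    bait_chrom = config.bait_chrom
    if bait_chrom not in rmap.sites:
        raise ValueError(f"bait chromosome {bait_chrom!r} not in map")
    n_bait = rmap.n_sites(bait_chrom)
    bait_idx = (
        config.bait_site_index if config.bait_site_index is not None else n_bait // 2
    )
    if not 0 <= bait_idx < n_bait:
        raise ValueError("bait site index outside the bait chromosome's site list")

    weights: dict[str, np.ndarray] = {}
    for chrom in rmap.chroms:
        pos = rmap.sites[chrom]
        if chrom == bait_chrom:
            d = np.abs(np.arange(len(pos)) - bait_idx).astype(float)
            w = np.power(1.0 + d, -config.alpha)
            w[bait_idx] = 0.0
        else:
            w = np.full(len(pos), config.trans_base)
        for region in config.planted:
            if region.chrom == chrom:
                inside = (pos >= region.start) & (pos < region.end)
                w = np.where(inside, w * region.weight, w)
        weights[chrom] = w

    chroms = rmap.chroms
    offsets, off = {}, 0
    for chrom in chroms:
        offsets[chrom] = off
        off += len(weights[chrom])
    flat = np.concatenate([weights[c] for c in chroms])
    total = flat.sum()
    if total <= 0:
        raise ValueError("degenerate mixture: total weight is zero")
    flat_probs = flat / total
    probs = {c: flat_probs[offsets[c] : offsets[c] + len(weights[c])] for c in chroms}
    return SimTruth(
        bait=(bait_chrom, bait_idx),
        planted=list(config.planted),
        chroms=chroms,
        probs=probs,
        offsets=offsets,
        flat_probs=flat_probs,
    )


def sample_partner_site(truth: SimTruth, rng: np.random.Generator, size=None):
    """Draw partner site(s) from the truth mixture (flat site indices)."""
    return rng.choice(len(truth.flat_probs), size=size, p=truth.flat_probs)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def _copies(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    # 1 + Geometric(rate) copies per molecule: P(total = k) = (1-rate) rate^(k-1).
    if rate == 0:
        return np.ones(n, dtype=np.int64)
    return rng.geometric(1.0 - rate, size=n)


def simulate_4c_reads(genome: dict[str, str], rmap: RestrictionMap, config: SimConfig):
    """Simulate a 4C library; returns ``(reads, truth)``.

    Each unique molecule is ``primer + first capture_end_length bp of the
    partner fragment`` (the fragment starting at the sampled partner site),
    trimmed to ``read_length``. The primer is the genomic sequence ending at
    the bait site, so every read carries it as an exact prefix. PCR
    duplication re-emits each molecule ``1 + Geometric`` times. Reads are
    ``(id, sequence, quality)`` with all-'I' Phred+33 qualities.
    """
    truth = build_truth(rmap, config)
    bait_chrom, bait_idx = truth.bait
    bait_pos = int(rmap.sites[bait_chrom][bait_idx])
    plen = config.primer_length
    if bait_pos < plen:
        raise ValueError("bait site too close to the chromosome start for the primer")
    primer = genome[bait_chrom][bait_pos - plen : bait_pos]
    occurrences = sum(len(find_sites(seq, primer)) for seq in genome.values())
    if occurrences != 1:
        raise ValueError(
            f"primer must occur exactly once in the genome (found {occurrences})"
        )

    rng_partner = _rng(config, 1)
    rng_dup = _rng(config, 2)
    rng_err = _rng(config, 5)
    gidx = sample_partner_site(truth, rng_partner, size=config.n_molecules)
    copies = _copies(rng_dup, config.duplication_rate, config.n_molecules)

    end_len = config.capture_end_length
    counts = {c: np.zeros(rmap.n_sites(c), dtype=np.int64) for c in rmap.chroms}
    reads = []
    for i, g in enumerate(gidx.tolist()):
        chrom, k = truth.site_of(g)
        counts[chrom][k] += 1
        fs, fe = rmap.fragment_of_site(chrom, k)
        pseq = genome[chrom][fs : fs + min(end_len, fe - fs)]
        seq = (primer + pseq)[: config.read_length]
        seq = _apply_errors(seq, config.substitution_rate, rng_err)
        qual = "I" * len(seq)
        for c in range(int(copies[i])):
            reads.append((f"mol{i}/{c}", seq, qual))
    truth.draw_counts = counts
    truth.n_molecules = config.n_molecules
    return reads, truth


@dataclass(frozen=True)
class MoleculeRecord:
    """Ground truth for one unique Capture-C molecule."""

    partner_chrom: str
    partner_site: int
    partner_start: int  # partner fragment interval
    partner_end: int
    vp_len: int  # viewpoint-side shear length (junction-anchored suffix)
    partner_len: int  # partner-side shear length (junction-anchored prefix)
    overlapping: bool  # mates share a central overlap


def simulate_capturec_reads(genome: dict[str, str], rmap: RestrictionMap, config: SimConfig):
    """Simulate a Capture-C library; returns ``(pairs, truth)``.

    Each unique molecule is a viewpoint sub-fragment (random-length suffix of
    the viewpoint fragment, ending at its downstream restriction site) joined
    to a partner sub-fragment (random-length prefix of the partner fragment,
    which begins with the restriction motif) — so in-silico digestion of the
    reconstructed read splits it at exactly the ligation junction. Shear
    lengths are rejection-sampled so no two unique molecules share the same
    sub-fragment composition, making composition-based deduplication exact on
    error-free data. Pairs are ``(id, seq1, qual1, seq2, qual2)``; mate 2 is
    the reverse complement of the molecule's other end.
    """
    truth = build_truth(rmap, config)
    bait_chrom, bait_idx = truth.bait
    enzyme = resolve_enzyme(config.enzyme)
    m = len(enzyme.motif)
    vstart, vend = rmap.fragment_of_site(bait_chrom, bait_idx)
    vp_interior = vend - (vstart + m)  # usable viewpoint suffix, motif excluded
    if vp_interior < 40:
        raise ValueError("viewpoint fragment too short for sub-fragment sampling")

    rng_partner = _rng(config, 1)
    rng_dup = _rng(config, 2)
    rng_shear = _rng(config, 3)
    rng_overlap = _rng(config, 4)
    rng_err = _rng(config, 5)

    gidx = sample_partner_site(truth, rng_partner, size=config.n_molecules)
    copies = _copies(rng_dup, config.duplication_rate, config.n_molecules)
    wants_overlap = rng_overlap.random(config.n_molecules) < config.overlap_fraction

    R = config.cc_read_length
    seen: set[tuple[int, int, int]] = set()
    pairs, molecules = [], []
    for i, g in enumerate(gidx.tolist()):
        chrom, k = truth.site_of(g)
        ps, pe = rmap.fragment_of_site(chrom, k)
        plen_max = pe - ps
        if wants_overlap[i]:
            # short molecule: guaranteed central overlap of the 2xR bp pair
            lo1, hi1 = 40, min(110, vp_interior)
            lo2, hi2 = 40, min(110, plen_max)
        else:
            lo1, hi1 = R + 1, min(R + 25, vp_interior)
            lo2, hi2 = R + 1, min(R + 25, plen_max)
            if lo1 > hi1 or lo2 > hi2:  # fragment too short for a long molecule
                lo1, hi1 = 40, min(110, vp_interior)
                lo2, hi2 = 40, min(110, plen_max)
        for _ in range(200):
            L1 = int(rng_shear.integers(lo1, hi1 + 1))
            L2 = int(rng_shear.integers(lo2, hi2 + 1))
            if (L1, g, L2) not in seen:
                break
        seen.add((L1, g, L2))
        mol = genome[bait_chrom][vend - L1 : vend] + genome[chrom][ps : ps + L2]
        r1 = _apply_errors(mol[:R], config.substitution_rate, rng_err)
        r2 = _apply_errors(revcomp(mol)[:R], config.substitution_rate, rng_err)
        q1, q2 = "I" * len(r1), "I" * len(r2)
        for c in range(int(copies[i])):
            pairs.append((f"mol{i}/{c}", r1, q1, r2, q2))
        molecules.append(
            MoleculeRecord(chrom, k, ps, pe, L1, L2, bool(wants_overlap[i]))
        )
    truth.molecules = molecules
    truth.n_molecules = config.n_molecules
    return pairs, truth


def partner_fragment_counts(truth: SimTruth, rmap: RestrictionMap) -> dict[str, np.ndarray]:
    """Per-fragment tallies of the generator's Capture-C partner draws."""
    if truth.molecules is None:
        raise ValueError("truth carries no Capture-C molecule log")
    counts = {c: np.zeros(rmap.n_fragments(c), dtype=np.int64) for c in rmap.chroms}
    for rec in truth.molecules:
        b = rmap.boundaries[rec.partner_chrom]
        j = int(np.searchsorted(b, rec.partner_start))
        counts[rec.partner_chrom][j] += 1
    return counts


def write_config(config: SimConfig, path) -> None:
    """Record a config as key = value lines (planted regions inlined)."""
    with open(path, "w") as fh:
        for key, value in vars(config).items():
            if key == "chrom_lengths":
                value = ",".join(f"{c}:{L}" for c, L in value.items())
            elif key == "planted":
                value = ";".join(
                    f"{r.chrom}:{r.start}-{r.end}:{r.weight}" for r in value
                )
            fh.write(f"{key} = {value}\n")


def read_config(path) -> SimConfig:
    """Parse a key = value config file written by :func:`write_config`."""
    kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "chrom_lengths":
                kwargs[key] = {
                    c: int(L)
                    for c, L in (item.split(":") for item in value.split(",") if item)
                }
            elif key == "planted":
                regions = []
                for item in filter(None, value.split(";")):
                    chrom, iv, weight = item.split(":")
                    start, end = iv.split("-")
                    regions.append(PlantedRegion(chrom, int(start), int(end), float(weight)))
                kwargs[key] = regions
            elif key in {"alpha", "trans_base", "duplication_rate", "overlap_fraction", "substitution_rate"}:
                kwargs[key] = float(value)
            elif key == "bait_site_index":
                kwargs[key] = None if value == "None" else int(value)
            elif key in {"enzyme", "bait_chrom"}:
                kwargs[key] = value
            else:
                kwargs[key] = int(value)
    return SimConfig(**kwargs)
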