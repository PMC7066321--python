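"""4C-seq interaction calling: binarized sliding-window Z-score model.

The analysis chain is: select primer-bearing reads, assign each captured
sequence to a restriction site, binarize per-site counts (presence/absence
suppresses PCR-duplication bias), then slide a foreground window of l_w
sites along each chromosome and score it against the expectation from a
larger background window of L_W sites:

    mu_W = (background indicator sum) * l_w / L_W
    z_i  = (C_i,w - mu_W) / sqrt(mu_W * (1 - mu_W / l_w))

C_i,w is the number of ligation-positive sites in the foreground window.
The variance term is binomial: C is a sum of l_w indicators with estimated
success rate mu_W / l_w. z is compared against the standard Gaussian;
one-sided upper-tail p-values below the significance level flag the site
(only enrichment is biologically meaningful for a viewpoint assay).

Cis calling uses a local background window (default 100/3000 sites, the
sizes appropriate for a mammalian chromosome); trans calling uses the whole
chromosome as background since no distance adjustment is needed there.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .digest import RestrictionMap
from .io import read_bed

logger = logging.getLogger(__name__)


@dataclass
class SiteIndicatorTrack:
    """Per-chromosome binary "ligation observed" vectors for one library.

    ``indicator[chrom][k]`` is 1 iff the raw count at site k is >= 1; raw
    counts are retained for diagnostics.
    """

    label: str
    counts: dict[str, np.ndarray]
    indicator: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, c in self.counts.items():
            c = np.asarray(c)
            if (c < 0).any():
                raise ValueError("raw counts must be non-negative")
            self.counts[chrom] = c
            self.indicator[chrom] = (c >= 1).astype(np.uint8)

    @property
    def chroms(self) -> list[str]:
        return list(self.counts)


@dataclass(frozen=True)
class WindowParams:
    """Foreground/background window sizes (in sites) and significance level."""

    l_w: int
    L_W: int | None = None
    whole_chromosome: bool = False
    alpha: float = 0.05

    def __post_init__(self):
        if self.l_w < 1:
            raise ValueError("foreground window must be >= 1 site")
        if not self.whole_chromosome:
            if self.L_W is None or self.L_W <= self.l_w:
                raise ValueError("background window must exceed the foreground window")


#: The window sizes used for intra-chromosomal (cis) calling.
CIS_DEFAULT = WindowParams(l_w=100, L_W=3000)
#: The window sizes used for inter-chromosomal (trans) calling.
TRANS_DEFAULT = WindowParams(l_w=500, whole_chromosome=True)


@dataclass(frozen=True)
class WindowStat:
    """The windowed statistic at one site. ``z`` is NaN for degenerate windows."""

    i: int
    C: int
    mu: float
    z: float
    p: float


@dataclass(frozen=True)
class InteractionCall:
    """A merged run of significant sites."""

    chrom: str
    start: int
    end: int
    n_sites: int
    peak_z: float
    min_p: float
    label: str = ""


def select_primer_reads(reads, primer: str, max_mismatches: int = 0):
    """Keep reads whose prefix matches the primer; return their suffixes.

    Parameters
    ----------
    reads : iterable
        Either plain sequences or ``(id, seq, qual)`` FASTQ tuples.
    primer : str
        The bait-specific primer; must be non-empty.
    max_mismatches : int
        Hamming mismatches tolerated in the prefix (0 = exact).

    Returns
    -------
    (captured, stats)
        ``captured``: list of read suffixes after the primer ("sub-fragments
        concatenated with primer sequences", primer removed);
        ``stats``: dict with ``kept`` and ``total`` read counts.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    plen = len(primer)
    captured, total = [], 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        total += 1
        if len(seq) < plen:
            continue
        prefix = seq[:plen]
        if max_mismatches == 0:
            ok = prefix == primer
        else:
            ok = sum(a != b for a, b in zip(prefix, primer)) <= max_mismatches
        if ok:
            captured.append(seq[plen:])
    return captured, {"kept": len(captured), "total": total}


def fragment_end_index(
    rmap: RestrictionMap, genome: dict[str, str], end_length: int = 40
):
    """Map each site's adjacent fragment-end sequence to its site identity.

    The fragment end of site k is the first ``end_length`` bp of the
    fragment starting at that site. Sequences shared by several sites are
    ambiguous and excluded (returned separately).
    """
    index: dict[str, tuple[str, int]] = {}
    ambiguous: set[str] = set()
    for chrom in rmap.chroms:
        for k in range(rmap.n_sites(chrom)):
            fs, fe = rmap.fragment_of_site(chrom, k)
            key = genome[chrom][fs : fs + min(end_length, fe - fs)]
            if key in index or key in ambiguous:
                ambiguous.add(key)
                index.pop(key, None)
            else:
                index[key] = (chrom, k)
    return index, ambiguous


def assign_sites(
    captured,
    rmap: RestrictionMap,
    genome: dict[str, str],
    end_length: int = 40,
):
    """Assign captured sequences to restriction sites by exact fragment-end match.

    Each sequence is trimmed to ``end_length`` bp and looked up against the
    fragment-end index; non-matching sequences are counted unassigned and
    ambiguous fragment ends are excluded and logged. Returns
    ``(counts, stats)`` with per-chromosome per-site raw counts.
    """
    index, ambiguous = fragment_end_index(rmap, genome, end_length)
    if ambiguous:
        logger.warning("%d ambiguous fragment-end sequences excluded", len(ambiguous))
    counts = {c: np.zeros(rmap.n_sites(c), dtype=np.int64) for c in rmap.chroms}
    stats = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
    for seq in captured:
        key = seq[:end_length]
        if key in ambiguous:
            stats["ambiguous"] += 1
        elif key in index:
            chrom, k = index[key]
            counts[chrom][k] += 1
            stats["assigned"] += 1
        else:
            stats["unassigned"] += 1
    return counts, stats


def counts_from_positions(rmap: RestrictionMap, positions) -> dict[str, np.ndarray]:
    """Per-site counts from pre-mapped coordinates (import path for real data).

    Each ``(chrom, pos)`` increments the site at the start of the fragment
    containing ``pos``; positions in a chromosome's first fragment (no
    upstream site) are skipped.
    """
    counts = {c: np.zeros(rmap.n_sites(c), dtype=np.int64) for c in rmap.chroms}
    for chrom, pos in positions:
        b = rmap.boundaries[chrom]
        j = int(np.searchsorted(b, pos, side="right")) - 1
        start = b[j]
        k = int(np.searchsorted(rmap.sites[chrom], start))
        sites = rmap.sites[chrom]
        if k < len(sites) and sites[k] == start:
            counts[chrom][k] += 1
    return counts


def counts_from_bed(rmap: RestrictionMap, path) -> dict[str, np.ndarray]:
    """BED import path: one count per interval, placed at its start position."""
    df = read_bed(path)
    return counts_from_positions(
        rmap, zip(df["chrom"].tolist(), df["start"].tolist())
    )


def binarize(counts: dict[str, np.ndarray], label: str = "library") -> SiteIndicatorTrack:
    """Reduce raw per-site counts to presence/absence (1 iff count >= 1)."""
    return SiteIndicatorTrack(label=label, counts=dict(counts))


def zscore_from_counts(C: float, l_w: float, bg_sum: float, L_W: float):
    """Evaluate the window statistic from its four ingredients.

    Returns ``(mu, z, p)``. Degenerate windows — expected count 0 (no
    evidence) or equal to the window size (zero variance) — return the
    non-significant sentinel ``(mu, nan, 1.0)``.
    """
    mu = bg_sum * l_w / L_W
    if mu <= 0 or mu >= l_w:
        return mu, float("nan"), 1.0
    z = (C - mu) / math.sqrt(mu * (1.0 - mu / l_w))
    return mu, z, float(sps.norm.sf(z))


def window_zscore(indicator: np.ndarray, i: int, params: WindowParams) -> WindowStat:
    """The window statistic at site ``i`` of one chromosome's indicator vector.

    The foreground window is l_w sites centered at i (half-width floored, so
    the effective window is the next odd size); the background window is L_W
    sites centered at i, or the whole chromosome. Both are truncated at
    chromosome ends, with the expectation rescaled by the realized lengths.
    """
    ind = np.asarray(indicator)
    n = len(ind)
    if not 0 <= i < n:
        raise IndexError(f"site index {i} outside [0, {n})")
    hw = params.l_w // 2
    lo, hi = max(0, i - hw), min(n, i + hw + 1)
    C = int(ind[lo:hi].sum())
    lfg = hi - lo
    if params.whole_chromosome:
        bg_sum, Lbg = int(ind.sum()), n
    else:
        HW = params.L_W // 2
        blo, bhi = max(0, i - HW), min(n, i + HW + 1)
        bg_sum, Lbg = int(ind[blo:bhi].sum()), bhi - blo
    mu, z, p = zscore_from_counts(C, lfg, bg_sum, Lbg)
    return WindowStat(i=i, C=C, mu=mu, z=z, p=p)


def _sliding_stats(ind: np.ndarray, params: WindowParams):
    """Vectorized window statistics for every site of one chromosome."""
    ind = np.asarray(ind, dtype=np.int64)
    n = len(ind)
    idx = np.arange(n)
    csum = np.concatenate(([0], np.cumsum(ind)))
    hw = params.l_w // 2
    lo, hi = np.maximum(0, idx - hw), np.minimum(n, idx + hw + 1)
    C = csum[hi] - csum[lo]
    lfg = (hi - lo).astype(float)
    if params.whole_chromosome:
        bg_sum = np.full(n, csum[n], dtype=float)
        Lbg = np.full(n, n, dtype=float)
    else:
        HW = params.L_W // 2
        blo, bhi = np.maximum(0, idx - HW), np.minimum(n, idx + HW + 1)
        bg_sum = (csum[bhi] - csum[blo]).astype(float)
        Lbg = (bhi - blo).astype(float)
    mu = bg_sum * lfg / Lbg
    valid = (mu > 0) & (mu < lfg)
    z = np.full(n, np.nan)
    z[valid] = (C[valid] - mu[valid]) / np.sqrt(mu[valid] * (1.0 - mu[valid] / lfg[valid]))
    p = np.ones(n)
    p[valid] = sps.norm.sf(z[valid])
    return C, mu, z, p, valid


@dataclass
class CallResult:
    """Per-site statistics and significance flags for one library."""

    stats: pd.DataFrame  # chrom, site, pos, C, mu, z, p, cis, evaluated, significant
    bait: tuple[str, int]
    skipped: list[str]
    cis_params: WindowParams
    trans_params: WindowParams
    exclusion_sites: int

    def flagged(self, chrom: str | None = None) -> dict[str, np.ndarray]:
        df = self.stats[self.stats["significant"]]
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        return {c: g["site"].to_numpy() for c, g in df.groupby("chrom", sort=False)}

    @property
    def n_evaluated(self) -> int:
        return int(self.stats["evaluated"].sum())

    @property
    def flagged_fraction(self) -> float:
        n = self.n_evaluated
        return float(self.stats["significant"].sum()) / n if n else float("nan")


def call_interactions(
    track: SiteIndicatorTrack,
    rmap: RestrictionMap,
    bait: tuple[str, int],
    cis_params: WindowParams = CIS_DEFAULT,
    trans_params: WindowParams = TRANS_DEFAULT,
    exclusion_sites: int = 10,
) -> CallResult:
    """Score every site on every chromosome and flag significant ones.

    The bait chromosome is scored with ``cis_params`` (local background);
    all other chromosomes with ``trans_params`` (whole-chromosome
    background). Sites within ``exclusion_sites`` of the bait are excluded
    from cis calls: the viewpoint's self-ligation/religation signal is
    unavoidable and uninformative. Chromosomes with fewer sites than the
    foreground window are skipped with a warning. Degenerate windows carry
    the non-significant sentinel and are not counted as evaluated.
    """
    bait_chrom, bait_idx = bait
    if bait_chrom not in track.counts:
        raise ValueError(f"bait chromosome {bait_chrom!r} not in track")
    frames, skipped = [], []
    for chrom in track.chroms:
        ind = track.indicator[chrom]
        is_cis = chrom == bait_chrom
        params = cis_params if is_cis else trans_params
        eff_fg = 2 * (params.l_w // 2) + 1
        if len(ind) < eff_fg:
            logger.warning(
                "chromosome %s has %d sites < foreground window %d: skipped",
                chrom, len(ind), eff_fg,
            )
            skipped.append(chrom)
            continue
        C, mu, z, p, valid = _sliding_stats(ind, params)
        evaluated = valid.copy()
        if is_cis:
            excluded = np.abs(np.arange(len(ind)) - bait_idx) <= exclusion_sites
            evaluated &= ~excluded
        significant = evaluated & (p < params.alpha)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "site": np.arange(len(ind)),
                    "pos": rmap.sites[chrom],
                    "C": C,
                    "mu": mu,
                    "z": z,
                    "p": p,
                    "cis": is_cis,
                    "evaluated": evaluated,
                    "significant": significant,
                }
            )
        )
    stats = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["chrom", "site", "pos", "C", "mu", "z", "p", "cis", "evaluated", "significant"]
        )
    )
    return CallResult(
        stats=stats,
        bait=bait,
        skipped=skipped,
        cis_params=cis_params,
        trans_params=trans_params,
        exclusion_sites=exclusion_sites,
    )


def merge_sites_to_regions(
    flagged: dict[str, np.ndarray],
    rmap: RestrictionMap,
    max_gap_sites: int = 1,
    stats: pd.DataFrame | None = None,
    label: str = "",
) -> list[InteractionCall]:
    """Merge runs of flagged sites into interaction regions.

    Consecutive flagged sites separated by at most ``max_gap_sites``
    unflagged sites join one region. A region spans from its first member
    site's position to the end of its last member site's fragment, so
    endpoints lie on restriction-site coordinates (or the chromosome end).
    Peak Z and minimum p are taken from ``stats`` when provided.
    """
    calls: list[InteractionCall] = []
    for chrom, idx in flagged.items():
        idx = np.sort(np.asarray(idx, dtype=np.int64))
        if idx.size == 0:
            continue
        breaks = np.nonzero(np.diff(idx) > max_gap_sites + 1)[0]
        groups = np.split(idx, breaks + 1)
        lookup = None
        if stats is not None:
            sub = stats[stats["chrom"] == chrom].set_index("site")
            lookup = sub
        for grp in groups:
            first, last = int(grp[0]), int(grp[-1])
            start = int(rmap.sites[chrom][first])
            _, end = rmap.fragment_of_site(chrom, last)
            peak_z, min_p = float("nan"), float("nan")
            if lookup is not None:
                zs = lookup.loc[grp, "z"].to_numpy(dtype=float)
                ps = lookup.loc[grp, "p"].to_numpy(dtype=float)
                peak_z = float(np.nanmax(zs)) if np.isfinite(zs).any() else float("nan")
                min_p = float(np.nanmin(ps))
            calls.append(
                InteractionCall(chrom, start, end, len(grp), peak_z, min_p, label)
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def _as_intervals(regions):
    out: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        if isinstance(r, InteractionCall):
            chrom, start, end = r.chrom, r.start, r.end
        else:
            chrom, start, end = r[0], int(r[1]), int(r[2])
        out.setdefault(chrom, []).append((start, end))
    for ivs in out.values():
        ivs.sort()
    return out


def overlap_replicates(regions_rep1, regions_rep2) -> list[tuple[str, int, int]]:
    """High-confidence regions: pairwise intersections of two replicates.

    Both inputs are interval lists (``InteractionCall`` or
    ``(chrom, start, end)``); within each replicate the called regions are
    non-overlapping. Every >= 1 bp intersection is returned trimmed to the
    intersecting interval, so the result is symmetric in content.
    """
    a, b = _as_intervals(regions_rep1), _as_intervals(regions_rep2)
    out = []
    for chrom in a:
        if chrom not in b:
            continue
        xs, ys = a[chrom], b[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                out.append((chrom, s, e))
            if xs[i][1] <= ys[j][1]:
                i += 1
            else:
                j += 1
    return sorted(set(out))


def annotate_genes(regions, genes: pd.DataFrame):
    """Genes overlapping (>= 1 bp) each region, plus the unique gene total.

    ``genes`` is a BED DataFrame (:func:`vpcontact.io.read_bed`). Returns
    ``(per_region, n_unique)`` where ``per_region`` lists gene names per
    region in input order; a gene spanning several regions counts once in
    the unique total.
    """
    by_chrom = {
        chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["name"].to_numpy())
        for chrom, g in genes.groupby("chrom", sort=False)
    }
    per_region: list[list[str]] = []
    unique: set[str] = set()
    intervals = []
    for r in regions:
        if isinstance(r, InteractionCall):
            intervals.append((r.chrom, r.start, r.end))
        else:
            intervals.append((r[0], int(r[1]), int(r[2])))
    for chrom, start, end in intervals:
        if chrom not in by_chrom:
            per_region.append([])
            continue
        gs, ge, gn = by_chrom[chrom]
        hit = (gs < end) & (ge > start)
        names = gn[hit].tolist()
        per_region.append(names)
        unique.update(names)
    return per_region, len(unique)


def write_stats_tsv(result: CallResult, path) -> None:
    result.stats.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(calls: list[InteractionCall], path) -> None:
    """Significant regions as BED6; score = -log10(min p), capped at 300."""
    from .io import write_bed

    rows = []
    for i, c in enumerate(calls):
        score = 300.0
        if c.min_p > 0:
            score = min(300.0, -math.log10(c.min_p))
        rows.append((c.chrom, c.start, c.end, c.label or f"region_{i}", f"{score:.3f}", "."))
    write_bed(rows, path)
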