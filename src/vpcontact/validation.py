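"""End-to-end validation scenarios on synthetic libraries.

These runners wire the simulator to the analysis modules at desk scale and
measure the pipeline's key operating characteristics: null calibration of
the window statistic, recovery of planted interaction hubs, invariance of
calls to PCR duplication, exactness of the Capture-C chain on error-free
reads, and differential-site detection. They are used both by the test
suite and by ``scripts/acceptance.py``.

Problem sizes: synthetic chromosomes carry a few hundred restriction sites,
so the window sizes here are scaled analogs of the chromosome-scale
defaults, chosen to keep foreground << background <= chromosome (the regime
the statistic assumes); see docs/methods.md.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .capture import (
    ViewpointSpec,
    class_counts,
    dedup_reads,
    differential_sites,
    process_pairs,
    reporter_profile,
)
from .digest import resolve_enzyme
from .fourc import (
    WindowParams,
    assign_sites,
    binarize,
    call_interactions,
    merge_sites_to_regions,
    select_primer_reads,
    zscore_from_counts,
)
from .simulate import PlantedRegion, SimConfig, make_genome, simulate_4c_reads, simulate_capturec_reads

# Scaled window parameters for synthetic chromosomes of a few hundred sites.
CIS_SCALED = WindowParams(l_w=11, L_W=121)
TRANS_SCALED = WindowParams(l_w=25, whole_chromosome=True)

#: 1 Mb null-calibration genome (same proportions as the 2.5 Mb default).
NULL_CHROMS = {"chr1": 400_000, "chr2": 200_000, "chr3": 200_000, "chr4": 200_000}


def _call_pipeline(config: SimConfig):
    """Simulate a 4C library and run the full calling chain."""
    genome, rmap, _ = make_genome(config)
    reads, truth = simulate_4c_reads(genome, rmap, config)
    bait_chrom, bait_idx = truth.bait
    bait_pos = int(rmap.sites[bait_chrom][bait_idx])
    primer = genome[bait_chrom][bait_pos - config.primer_length : bait_pos]
    captured, _ = select_primer_reads(reads, primer)
    counts, _ = assign_sites(captured, rmap, genome, config.capture_end_length)
    track = binarize(counts, label=f"sim_seed{config.seed}")
    result = call_interactions(
        track, rmap, truth.bait, cis_params=CIS_SCALED, trans_params=TRANS_SCALED
    )
    return genome, rmap, truth, track, result


def null_calibration(seed: int, n_sims: int = 20, n_reads: int = 50_000):
    """Type-I calibration: flagged-site fraction under the null mixture.

    Runs ``n_sims`` simulations with no planted regions on a 1 Mb genome at
    1 kb site spacing and measures, per simulation, the fraction of
    evaluated sites (those carrying a defined, non-degenerate statistic)
    flagged at the 0.05 significance level. Returns a dict with the
    per-simulation fractions, their mean, and the Monte-Carlo standard
    error of the mean.
    """
    fractions, evaluated = [], 0
    for j in range(n_sims):
        config = SimConfig(
            chrom_lengths=dict(NULL_CHROMS),
            n_molecules=n_reads,
            seed=(seed * 1009 + j) % (2**31 - 1),
        )
        *_, result = _call_pipeline(config)
        fractions.append(result.flagged_fraction)
        evaluated += result.n_evaluated
    fractions = np.asarray(fractions)
    return {
        "fractions": fractions,
        "mean": float(fractions.mean()),
        "se": float(fractions.std(ddof=1) / np.sqrt(n_sims)),
        "alpha": 0.05,
        "n_evaluated": evaluated,
    }


def _recovery_regions(config_probe: SimConfig):
    """5 cis + 5 trans planted regions for the default 2.5 Mb genome.

    Cis hubs are placed beyond the bait-proximal religation shoulder, where
    per-site coverage leaves dynamic range for enrichment. With the default
    decay (alpha=2) at 1e5 reads the expected per-site molecule count is
    ~7.7e4/d^2, so binarized occupancy stays near 1 out to d ~ 250 sites;
    hubs go at 260-450 sites from the bait. Trans hubs are spread over the
    three trans chromosomes.
    """
    spacing = config_probe.spacing
    bait_bp = (config_probe.chrom_lengths["chr1"] // spacing // 2) * spacing
    width = 20 * spacing  # ~20 sites per hub
    cis_offsets = [260, -300, 340, -390, 450]
    regions = [
        PlantedRegion("chr1", bait_bp + off * spacing, bait_bp + off * spacing + width, 10.0)
        for off in cis_offsets
    ]
    regions += [
        PlantedRegion("chr2", 100_000, 100_000 + width, 10.0),
        PlantedRegion("chr2", 350_000, 350_000 + width, 10.0),
        PlantedRegion("chr3", 150_000, 150_000 + width, 10.0),
        PlantedRegion("chr4", 100_000, 100_000 + width, 10.0),
        PlantedRegion("chr4", 300_000, 300_000 + width, 10.0),
    ]
    return regions


def planted_recovery(seed: int, n_seeds: int = 5, n_reads: int = 100_000):
    """Recovery of planted hubs: fraction overlapping a called region.

    Per seed: simulate 100k reads with 5 cis and 5 trans planted regions of
    weight 10, call interactions, merge flagged sites into regions
    (gap 1), and score a planted region as recovered if any called region
    overlaps it by >= 1 bp. Returns per-seed recovery fractions.
    """
    base = SimConfig()
    regions = _recovery_regions(base)
    per_seed = []
    for j in range(n_seeds):
        config = replace(
            base,
            planted=regions,
            n_molecules=n_reads,
            seed=(seed * 2003 + j) % (2**31 - 1),
        )
        _, rmap, truth, _, result = _call_pipeline(config)
        calls = merge_sites_to_regions(
            result.flagged(), rmap, max_gap_sites=1, stats=result.stats
        )
        recovered = 0
        for region in regions:
            hit = any(
                c.chrom == region.chrom and c.start < region.end and c.end > region.start
                for c in calls
            )
            recovered += hit
        per_seed.append(recovered / len(regions))
    return {"per_seed": np.asarray(per_seed), "n_regions": len(regions)}


def duplication_invariance(seed: int, n_reads: int = 20_000):
    """Identical calls at duplication 0 vs 0.5 with shared molecule draws.

    Binarization should neutralize PCR duplication entirely: the molecule
    stream is seed-shared, only the copy counts differ. Returns the number
    of sites whose significance flag differs, and the flagged counts.
    """
    flagged = {}
    n_sites = 0
    for rate in (0.0, 0.5):
        config = SimConfig(
            chrom_lengths=dict(NULL_CHROMS),
            n_molecules=n_reads,
            duplication_rate=rate,
            seed=seed % (2**31 - 1),
        )
        *_, result = _call_pipeline(config)
        key = result.stats.set_index(["chrom", "site"])["significant"]
        flagged[rate] = key
        n_sites = len(key)
    diff = int((flagged[0.0] != flagged[0.5]).sum())
    return {
        "n_differing": diff,
        "n_sites": n_sites,
        "n_flagged": int(flagged[0.0].sum()),
    }


def _capturec_config(seed: int, **overrides) -> SimConfig:
    base = dict(
        chrom_lengths=dict(NULL_CHROMS),
        enzyme="DpnII",
        n_molecules=1000,
        duplication_rate=0.5,
        overlap_fraction=1.0,
        seed=seed % (2**31 - 1),
    )
    base.update(overrides)
    return SimConfig(**base)


def _viewpoint(rmap, truth) -> ViewpointSpec:
    chrom, idx = truth.bait
    start, end = rmap.fragment_of_site(chrom, idx)
    return ViewpointSpec(chrom, start, end, flank=1000)


def capturec_exactness(seed: int, n_molecules: int = 1000):
    """Exactness of the Capture-C chain on error-free reads.

    Simulates ``n_molecules`` molecules at duplication 0.5, runs filter /
    merge / digest / map / classify / dedup / profile, and checks the exact
    bookkeeping identities: dedup survivors equal the molecule count, every
    mapped sub-fragment carries exactly one class, the bedGraph sum equals
    the reporter count, and per-fragment counts equal the generator's own
    partner tallies (restricted to reporter-eligible fragments).
    """
    config = _capturec_config(seed, n_molecules=n_molecules)
    genome, rmap, _ = make_genome(config)
    pairs, truth = simulate_capturec_reads(genome, rmap, config)
    vp = _viewpoint(rmap, truth)
    motif = resolve_enzyme(config.enzyme).motif
    records, _ = process_pairs(pairs, genome, vp, motif)
    unique = dedup_reads(records)
    counts = class_counts(unique)
    mapped = counts["capture"] + counts["proximity_exclusion"] + counts["reporter"]
    total_subfrags = sum(len(r.subfragments) for r in unique)
    profile, n_reporters = reporter_profile(unique, rmap)
    bedgraph_sum = int(sum(v.sum() for v in profile.values()))

    # Independent expectation: apply the classification rule to each truth
    # molecule's partner sub-fragment (the junction-anchored sheared piece).
    expected = {c: np.zeros(rmap.n_fragments(c), dtype=np.int64) for c in rmap.chroms}
    for rec in truth.molecules:
        s, e = rec.partner_start, rec.partner_start + rec.partner_len
        if rec.partner_chrom == vp.chrom and s < vp.end + vp.flank and e > vp.start - vp.flank:
            continue  # capture or proximity-exclusion class: not a reporter
        b = rmap.boundaries[rec.partner_chrom]
        j = int(np.searchsorted(b, (s + e) // 2, side="right")) - 1
        expected[rec.partner_chrom][j] += 1
    tally_mismatches = int(
        sum(np.abs(profile[c] - expected[c]).sum() for c in rmap.chroms)
    )
    return {
        "n_molecules": config.n_molecules,
        "n_pairs": len(pairs),
        "survivors": len(unique),
        "partition_violations": total_subfrags - mapped - counts["unmapped"],
        "unmapped": counts["unmapped"],
        "bedgraph_sum": bedgraph_sum,
        "n_reporters": n_reporters,
        "tally_mismatches": tally_mismatches,
    }


def classification_cases():
    """The three worked classification cases at the quoted 1 kb flank."""
    from .capture import SubFragment, classify_subfragment

    vp = ViewpointSpec("chrN", 10_000, 12_000, flank=1000)
    inside = SubFragment("r", 0, "chrN", 10_500, 10_600, "+")
    flank = SubFragment("r", 0, "chrN", 12_500, 12_600, "+")
    far = SubFragment("r", 0, "chrN", 50_000, 50_100, "+")
    other = SubFragment("r", 0, "chrM", 50_000, 50_100, "+")
    return (
        classify_subfragment(inside, vp),
        classify_subfragment(flank, vp),
        classify_subfragment(far, vp),
        classify_subfragment(other, vp),
    )


def differential_detection(seed: int, n_molecules: int = 4000, n_reps: int = 2):
    """Differential-site detection between two Capture-C conditions.

    The conditions share the genome and differ only in one planted cis hub
    (weight 1 in A vs 20 in B) placed 20-40 sites from the viewpoint, where
    baseline coverage supports count-based testing at these molecule
    numbers. Returns hub recall among significant fragments, direction
    correctness, the non-hub extras, and the label-swap comparison.
    """
    base = _capturec_config(seed, n_molecules=n_molecules)
    spacing = base.spacing
    bait_bp = (base.chrom_lengths["chr1"] // spacing // 2) * spacing
    hub = PlantedRegion("chr1", bait_bp + 20 * spacing, bait_bp + 41 * spacing, 20.0)
    genome, rmap, _ = make_genome(base)
    vp_truth = None
    motif = resolve_enzyme(base.enzyme).motif

    def run_condition(planted, rep_offset):
        nonlocal vp_truth
        profiles = []
        for r in range(n_reps):
            config = replace(
                base,
                planted=planted,
                seed=(base.seed + 7919 * (rep_offset + r) + 1) % (2**31 - 1),
            )
            pairs, truth = simulate_capturec_reads(genome, rmap, config)
            vp_truth = truth
            vp = _viewpoint(rmap, truth)
            records, _ = process_pairs(pairs, genome, vp, motif)
            unique = dedup_reads(records)
            profile, _ = reporter_profile(unique, rmap)
            profiles.append(profile)
        return profiles

    profiles_a = run_condition([], 0)
    profiles_b = run_condition([hub], n_reps)
    hits = differential_sites(profiles_a, profiles_b, rmap, fdr=0.05)
    swapped = differential_sites(profiles_b, profiles_a, rmap, fdr=0.05)

    def in_hub(row):
        return row["chrom"] == hub.chrom and row["start"] < hub.end and row["end"] > hub.start

    hub_hits = hits[[in_hub(r) for _, r in hits.iterrows()]] if len(hits) else hits
    extra_hits = hits[[not in_hub(r) for _, r in hits.iterrows()]] if len(hits) else hits
    extras = len(extra_hits)
    # Spurious extras are enriched-in-B fragments outside the hub; depleted
    # (direction A) extras are the expected compositional echo of the hub.
    extras_direction_b = int((extra_hits["direction"] == "B").sum()) if extras else 0
    # Expected detectable hub fragments: those actually enriched in condition B.
    b_pooled = np.sum(
        [np.concatenate([p[c] for c in rmap.chroms]) for p in profiles_b], axis=0
    )
    frag_idx, off = {}, 0
    for chrom in rmap.chroms:
        bd = rmap.boundaries[chrom]
        for j in range(rmap.n_fragments(chrom)):
            frag_idx[(chrom, int(bd[j]), int(bd[j + 1]))] = off
            off += 1
    hub_frag_keys = [
        key
        for key in frag_idx
        if key[0] == hub.chrom and key[1] < hub.end and key[2] > hub.start
    ]
    detectable = [k for k in hub_frag_keys if b_pooled[frag_idx[k]] >= 10]
    found = {
        (r["chrom"], r["start"], r["end"]) for _, r in hub_hits.iterrows()
    }
    recall = (
        sum(1 for k in detectable if k in found) / len(detectable) if detectable else 0.0
    )
    direction_ok = bool((hub_hits["direction"] == "B").all()) if len(hub_hits) else False
    swap_ok = set(map(tuple, hits[["chrom", "start", "end"]].to_numpy())) == set(
        map(tuple, swapped[["chrom", "start", "end"]].to_numpy())
    ) and (
        len(hits) == 0
        or (
            hits.sort_values(["chrom", "start"])["direction"].to_numpy()
            != swapped.sort_values(["chrom", "start"])["direction"].to_numpy()
        ).all()
    )
    return {
        "n_significant": len(hits),
        "hub_recall": float(recall),
        "n_detectable_hub_fragments": len(detectable),
        "extras": extras,
        "extras_direction_b": extras_direction_b,
        "direction_ok": direction_ok,
        "swap_symmetric": bool(swap_ok),
    }


def interval_oracles(seed: int, n_fixtures: int = 100):
    """Brute-force cross-checks of the interval/digest primitives.

    Each primitive is compared against an independent naive implementation
    on ``n_fixtures`` random fixtures; returns per-primitive disagreement
    counts (all zero when the implementations agree).
    """
    import pandas as pd

    from .digest import digest, find_sites, locate_fragment, resolve_enzyme
    from .fourc import annotate_genes, merge_sites_to_regions, overlap_replicates

    rng = np.random.default_rng(seed % (2**31 - 1))
    bases = np.array(list("ACGTN"))
    report = {k: 0 for k in ("find_sites", "locate_fragment", "merge", "overlap", "annotate")}

    # find_sites vs character-by-character scan on random 10 kb sequences
    for _ in range(n_fixtures):
        seq = "".join(rng.choice(bases, size=10_000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        motif = "".join(rng.choice(bases[:4], size=int(rng.integers(4, 7))))
        naive = [
            i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
        ]
        report["find_sites"] += find_sites(seq, motif) != naive

    # locate_fragment vs linear scan
    genome = {"c": "".join(rng.choice(bases[:4], size=30_000))}
    rmap = digest(genome, resolve_enzyme("DpnII"))
    frags = rmap.fragments("c")
    for pos in rng.integers(0, 30_000, size=n_fixtures).tolist():
        naive = next((s, e) for s, e in frags if s <= pos < e)
        report["locate_fragment"] += locate_fragment(rmap, "c", pos) != naive

    # merge_sites_to_regions vs greedy grouping
    toy = digest({"c": ("A" * 26 + "GATC") * 80}, resolve_enzyme("DpnII"))
    for _ in range(n_fixtures):
        gap = int(rng.integers(0, 4))
        idx = np.unique(rng.integers(0, 70, size=int(rng.integers(1, 25))))
        groups: list[list[int]] = []
        for k in idx.tolist():
            if groups and k - groups[-1][-1] <= gap + 1:
                groups[-1].append(k)
            else:
                groups.append([k])
        calls = merge_sites_to_regions({"c": idx}, toy, max_gap_sites=gap)
        ok = [c.n_sites for c in calls] == [len(g) for g in groups] and all(
            c.start == int(toy.sites["c"][g[0]]) for c, g in zip(calls, groups)
        )
        report["merge"] += not ok

    # overlap_replicates / annotate_genes vs all-pairs scans
    def random_regions():
        out, prev = [], 0
        for s in np.sort(rng.choice(300, size=int(rng.integers(1, 12)), replace=False)).tolist():
            s = max(s, prev)
            e = s + int(rng.integers(1, 20))
            out.append(("c", s, e))
            prev = e
        return out

    for _ in range(n_fixtures):
        r1, r2 = random_regions(), random_regions()
        brute = sorted(
            {
                ("c", max(s1, s2), min(e1, e2))
                for _, s1, e1 in r1
                for _, s2, e2 in r2
                if max(s1, s2) < min(e1, e2)
            }
        )
        report["overlap"] += overlap_replicates(r1, r2) != brute

        genes = pd.DataFrame(
            [
                ("c", int(s), int(s + rng.integers(1, 30)), f"g{i}", "+")
                for i, s in enumerate(rng.integers(0, 320, size=10))
            ],
            columns=["chrom", "start", "end", "name", "strand"],
        )
        per_region, n_unique = annotate_genes(r1, genes)
        expected_unique = set()
        ok = True
        for (_, rs, re_), hits_ in zip(r1, per_region):
            naive = [
                row["name"]
                for _, row in genes.iterrows()
                if row["start"] < re_ and row["end"] > rs
            ]
            ok &= sorted(hits_) == sorted(naive)
            expected_unique.update(naive)
        ok &= n_unique == len(expected_unique)
        report["annotate"] += not ok
    return report


def zscore_grid(n_min: int = 1000):
    """Max deviation of the window statistic from direct formula evaluation.

    Sweeps a grid of (C, l_w, background sum, L_W) combinations and compares
    :func:`zscore_from_counts` against independent inline arithmetic.
    """
    import math

    from scipy.stats import norm

    max_dev = 0.0
    n = 0
    for l_w in (3, 5, 10, 20, 50, 100):
        for L_W in (2 * l_w, 5 * l_w, 30 * l_w):
            for bg in range(0, L_W + 1, max(1, L_W // 10)):
                for C in range(0, l_w + 1, max(1, l_w // 5)):
                    mu, z, p = zscore_from_counts(C, l_w, bg, L_W)
                    mu_ref = bg * l_w / L_W
                    n += 1
                    if 0 < mu_ref < l_w:
                        z_ref = (C - mu_ref) / math.sqrt(mu_ref * (1 - mu_ref / l_w))
                        p_ref = float(norm.sf(z_ref))
                        max_dev = max(max_dev, abs(z - z_ref), abs(p - p_ref), abs(mu - mu_ref))
                    else:
                        assert math.isnan(z) and p == 1.0
    assert n >= n_min
    return {"max_dev": max_dev, "n": n}
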