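"""Synthetic ATAC-seq studies with known ground truth.

The generator emulates the statistical structure of a two-condition islet
maturation experiment (P10 vs adult, 3 replicates each): accessible
chromatin sites (ACS) with planted transcription-factor motif instances,
a linear activity model turning motif content into a true accessibility
log2 fold-change, negative-binomial replicate counts driven by that
fold-change, per-sample fragment intervals consistent with the counts,
and a gene expression fold-change table whose genes respond to their
linked ACS as enhancers or repressors.

Every draw flows from one integer seed through ``numpy.random.default_rng``
so regeneration is byte-identical, and the full ground truth (planted
match matrix, per-motif activities, per-ACS noise, gene roles) is carried
in a :class:`SyntheticTruth` that serializes losslessly to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .formats import ALPHABET, PWM, Region, reverse_complement

_MAX_PWM_WIDTH = 25


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SyntheticTruth:
    """Everything the generator decided, for downstream recovery checks.

    ``acs_log2fc_true = match_truth @ true_activity + noise`` holds exactly
    (the realized noise vector is stored).
    """

    seed: int
    motif_ids: list = field(default_factory=list)
    true_activity: list = field(default_factory=list)   # per motif, log2FC per match
    acs_ids: list = field(default_factory=list)
    match_truth_rows: list = field(default_factory=list)  # "0"/"1" strings, ACS x motif
    acs_log2fc_true: list = field(default_factory=list)
    noise: list = field(default_factory=list)           # realized Gaussian residuals
    noise_sd: float = 0.0
    planted_instances: list = field(default_factory=list)  # [acs_id, motif_id, pos, strand, word]
    dispersion: float | None = None
    lib_sizes: list | None = None                       # realized per-sample totals
    group_labels: dict | None = None                    # sample -> condition
    gene_truth: dict | None = None                      # gene -> {log2fc, role, acs_id}
    params: dict = field(default_factory=dict)

    @property
    def match_truth(self) -> np.ndarray:
        return np.array([[int(c) for c in row] for row in self.match_truth_rows],
                        dtype=np.int64)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticTruth":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (ValueError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    data = json.load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# motifs


def _column_ic(u: float) -> float:
    """IC in bits of the column (1-3u, u, u, u) against uniform background."""
    if u <= 0:
        return 2.0
    p = np.array([1 - 3 * u, u, u, u])
    return float(2.0 + np.sum(p * np.log2(p)))


def _solve_u(target_ic: float) -> float:
    lo, hi = 0.0, 0.25
    for _ in range(60):
        mid = (lo + hi) / 2
        if _column_ic(mid) > target_ic:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def sample_pwm(width: int, information_content: float, seed: int,
               motif_id: str = "M1") -> PWM:
    """Random PWM whose mean per-column IC matches the request.

    Each column concentrates mass ``1 - 3u`` on one random preferred base,
    with ``u`` solved so the column's information content equals the
    requested value (plus a small per-column jitter that preserves the
    mean).  ``information_content`` of 2 bits forces point-mass columns.
    """
    if not 4 <= width <= _MAX_PWM_WIDTH:
        raise ValueError(f"width must be in [4, {_MAX_PWM_WIDTH}], got {width}")
    if not 0 < information_content <= 2:
        raise ValueError("information_content must be in (0, 2]")
    rng = np.random.default_rng(seed)
    if information_content >= 2.0:  # point-mass columns, no jitter possible
        jitter = np.zeros(width)
    else:
        jitter = rng.normal(0, 0.05, size=width)
        jitter -= jitter.mean()
    targets = np.clip(information_content + jitter, 0.02, 2.0)
    matrix = np.zeros((4, width))
    for j in range(width):
        u = _solve_u(float(targets[j]))
        col = np.full(4, u)
        col[rng.integers(4)] = 1 - 3 * u
        matrix[:, j] = col
    return PWM(id=motif_id, matrix=matrix, name=motif_id)


def sample_motif_collection(n_motifs: int, seed: int, width_range=(8, 14),
                            ic_range=(1.1, 1.6)) -> list[PWM]:
    """A family of random PWMs with varied widths and information contents."""
    rng = np.random.default_rng(seed)
    pwms = []
    for m in range(n_motifs):
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        ic = float(rng.uniform(*ic_range))
        pwms.append(sample_pwm(w, ic, seed=int(rng.integers(2**31)),
                               motif_id=f"motif_{m + 1:03d}"))
    return pwms


# ---------------------------------------------------------------------------
# ACS sequences with planted instances


def _layout_regions(lengths: np.ndarray, gap: int, per_chrom: int = 500
                    ) -> list[Region]:
    regions = []
    pos, chrom_no = gap, 1
    for i, ln in enumerate(lengths):
        if i and i % per_chrom == 0:
            chrom_no += 1
            pos = gap
        regions.append(Region(f"chrS{chrom_no}", pos, pos + int(ln),
                              f"acs_{i + 1:05d}"))
        pos += int(ln) + gap
    return regions


def generate_acs_set(n_acs: int, length_range=(250, 450), gc: float = 0.45,
                     pwms: list[PWM] | None = None, planting_prob=0.1,
                     activities=None, noise_sd: float = 0.5, seed: int = 0,
                     gap: int = 120_000, instance_bias: float = 2.0):
    """Generate ACS sequences/regions with planted motif instances.

    Each motif is planted in each ACS with its planting probability, at a
    uniform non-overlapping position and random strand; planted instances
    are present verbatim (or reverse-complemented) in the sequence, over an
    i.i.d. background of the requested GC content.  The true accessibility
    change is ``match_truth @ activities + Normal(0, noise_sd)``.

    Planted instances are drawn from the PWM sharpened by the inverse
    temperature ``instance_bias`` (per-column probabilities proportional
    to ``p**instance_bias``): genomic sites that are actually bound are
    affinity-biased relative to the PWM, which averages over all
    occurrences.  ``instance_bias = 1`` samples the PWM as-is.

    Returns ``(sequences, regions, truth)`` where sequences are
    ``(id, seq)`` pairs and truth is a partial :class:`SyntheticTruth`.
    """
    if n_acs < 1:
        raise ValueError("n_acs must be >= 1")
    pwms = pwms or []
    lo, hi = length_range
    widest = max((p.width for p in pwms), default=0)
    if widest >= lo:
        raise ValueError(f"motif width {widest} >= minimum ACS length {lo}")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    prob = np.broadcast_to(np.asarray(planting_prob, dtype=float),
                           (len(pwms),)).copy()
    if activities is None:
        activities = np.zeros(len(pwms))
    activities = np.asarray(activities, dtype=float)
    bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lengths = rng.integers(lo, hi + 1, size=n_acs)
    regions = _layout_regions(lengths, gap)
    sequences = []
    match = np.zeros((n_acs, len(pwms)), dtype=np.int64)
    planted = []
    for i in range(n_acs):
        L = int(lengths[i])
        seq = rng.choice(4, size=L, p=bg)
        occupied = np.zeros(L, dtype=bool)
        for m, pwm in enumerate(pwms):
            if rng.random() >= prob[m]:
                continue
            w = pwm.width
            sharp = pwm.probabilities ** instance_bias
            sharp /= sharp.sum(axis=0, keepdims=True)
            inst = np.array([rng.choice(4, p=sharp[:, j]) for j in range(w)])
            if rng.random() < 0.5:
                inst = 3 - inst[::-1]  # reverse complement in code space
            placed = False
            for _ in range(50):
                pos = int(rng.integers(0, L - w + 1))
                if not occupied[pos:pos + w].any():
                    seq[pos:pos + w] = inst
                    occupied[pos:pos + w] = True
                    placed = True
                    break
            if placed:
                match[i, m] = 1
                planted.append([regions[i].id, pwm.id, pos, "+",
                                "".join(ALPHABET[b] for b in inst)])
        sequences.append((regions[i].id, "".join(ALPHABET[b] for b in seq)))
    noise = rng.normal(0, noise_sd, size=n_acs) if noise_sd > 0 \
        else np.zeros(n_acs)
    log2fc = match @ activities + noise
    truth = SyntheticTruth(
        seed=seed,
        motif_ids=[p.id for p in pwms],
        true_activity=list(map(float, activities)),
        acs_ids=[r.id for r in regions],
        match_truth_rows=["".join(map(str, row)) for row in match],
        acs_log2fc_true=list(map(float, log2fc)),
        noise=list(map(float, noise)),
        noise_sd=float(noise_sd),
        planted_instances=planted,
        params={"n_acs": n_acs, "length_range": list(length_range), "gc": gc,
                "planting_prob": list(map(float, prob)), "gap": gap,
                "instance_bias": instance_bias},
    )
    return sequences, regions, truth


# ---------------------------------------------------------------------------
# counts and fragments


def simulate_counts(truth: SyntheticTruth, n_per_group: int = 3,
                    baseline_logmean_sd: float = 0.8, seed: int = 0,
                    dispersion: float = 0.2, mean_count: float = 100.0,
                    lib_factor_sd: float = 0.1) -> pd.DataFrame:
    """Replicate NB count matrix driven by the true per-ACS log2 fold-change.

    ``counts[i, j] ~ NB(mean = lib_j * mu_i * 2**(x_j * log2fc_i), phi)``
    with ``x_j = 1`` for adult samples and 0 for P10, per-ACS baselines
    ``mu_i = mean_count * 2**Normal(0, baseline_logmean_sd)`` and mild
    lognormal library-size variation.  ``phi = 0`` gives Poisson counts.
    Updates ``truth`` with the dispersion, realized library sizes and group
    labels; returns a DataFrame (ACS x samples) with
    ``attrs['groups']`` set.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    log2fc = np.asarray(truth.acs_log2fc_true, dtype=float)
    n_acs = len(log2fc)
    samples = [f"P10_{k + 1}" for k in range(n_per_group)] + \
              [f"adult_{k + 1}" for k in range(n_per_group)]
    x = np.array([0] * n_per_group + [1] * n_per_group)
    mu = mean_count * 2 ** rng.normal(0, baseline_logmean_sd, size=n_acs)
    lib_rel = np.exp(rng.normal(0, lib_factor_sd, size=len(samples)))
    if (lib_rel <= 0).any():
        raise ValueError("library factors must be positive")
    mean = lib_rel[None, :] * mu[:, None] * 2 ** (x[None, :] * log2fc[:, None])
    if dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    df = pd.DataFrame(counts.astype(np.int64), columns=samples,
                      index=pd.Index(truth.acs_ids, name="acs_id"))
    groups = {s: ("adult" if xi else "P10") for s, xi in zip(samples, x)}
    df.attrs["groups"] = groups
    truth.dispersion = float(dispersion)
    truth.lib_sizes = [int(v) for v in df.sum(axis=0)]
    truth.group_labels = groups
    truth.params.update({"n_per_group": n_per_group, "mean_count": mean_count,
                         "baseline_logmean_sd": baseline_logmean_sd})
    return df


def simulate_fragments(regions, counts: pd.DataFrame, seed: int = 0,
                       size_modes=(80, 260), size_weights=(0.7, 0.3),
                       size_sd=(15, 40)) -> dict:
    """Per-sample fragment intervals consistent with the planned counts.

    For every planned insertion a fragment is laid with its 5' insertion
    point uniform inside the ACS and a length drawn from a two-mode
    mixture (nucleosome-free and mono-nucleosome), so insertion counting
    recovers approximately the planned matrix.
    """
    rng = np.random.default_rng(seed)
    region_by_id = {r.id: r for r in regions}
    out = {}
    for sample in counts.columns:
        frags = []
        col = counts[sample]
        for acs_id, c in col.items():
            r = region_by_id[acs_id]
            if c == 0:
                continue
            starts = rng.integers(r.start, r.end, size=int(c))
            modes = rng.choice(len(size_modes), size=int(c), p=size_weights)
            sizes = np.maximum(
                20, rng.normal(np.take(size_modes, modes),
                               np.take(size_sd, modes)).astype(np.int64))
            for s, ln in zip(starts, sizes):
                frags.append(Region(r.chrom, int(s), int(s + ln),
                                    f"{sample}_f{len(frags) + 1}"))
        out[sample] = frags
    return out


# ---------------------------------------------------------------------------
# genes


def make_tss_table(regions, seed: int = 0, class_probs=(0.34, 0.33, 0.33),
                   distal_max: int = 50_000) -> pd.DataFrame:
    """One gene per ACS, with TSS placed in the TSS/proximal/distal band.

    Offsets are sampled within |d| <= 1 kb (TSS class), 1-10 kb (proximal)
    or 10 kb-``distal_max`` (distal) of the ACS midpoint, on a random side
    and strand.  Region spacing in the generator is wide enough that each
    gene's nearest ACS is its own.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, r in enumerate(regions):
        band = rng.choice(3, p=class_probs)
        if band == 0:
            d = int(rng.integers(0, 1001))
        elif band == 1:
            d = int(rng.integers(1001, 10001))
        else:
            d = int(rng.integers(10001, distal_max + 1))
        side = 1 if rng.random() < 0.5 else -1
        strand = "+" if rng.random() < 0.5 else "-"
        tss = max(0, r.midpoint + side * d)
        rows.append((f"gene_{i + 1:05d}", r.chrom, strand, tss))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"]
                        ).set_index("gene_id")


def simulate_expression(gene_table: pd.DataFrame, links: dict,
                        acs_log2fc_true, role_design=(0.4, 0.2),
                        coupling: float = 0.8, noise_sd: float = 0.2,
                        seed: int = 0, truth: SyntheticTruth | None = None
                        ) -> pd.DataFrame:
    """Gene log2FC/FDR table with enhancer/repressor concordance.

    ``links`` maps acs_id -> gene_id; every linked gene is assigned a role
    with probabilities ``role_design = (enhancer, repressor)`` (the rest,
    and all unlinked genes, are 'none').  Enhancer genes move with their
    ACS (``+coupling * acs_log2fc``), repressor genes against it, plus
    Gaussian noise; 'none' genes are pure noise.  Roles come with a
    synthetic significance column: responding genes get FDR < 0.05.
    """
    f_enh, f_rep = role_design
    if f_enh < 0 or f_rep < 0 or f_enh + f_rep > 1:
        raise ValueError("role_design fractions must be non-negative, sum <= 1")
    rng = np.random.default_rng(seed)
    if isinstance(acs_log2fc_true, pd.Series):
        acs_fc = acs_log2fc_true.astype(float)
    else:  # plain vector: aligned with the links' iteration order
        acs_fc = pd.Series(np.asarray(acs_log2fc_true, dtype=float),
                           index=list(links.keys()))
    gene_of = {}
    for acs_id, gene_id in links.items():
        if gene_id not in gene_table.index:
            raise KeyError(f"link target {gene_id!r} not in gene table")
        gene_of[gene_id] = acs_id
    log2fc = {}
    roles = {}
    for gene_id in gene_table.index:
        eps = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
        if gene_id in gene_of:
            u = rng.random()
            fc_acs = float(acs_fc.loc[gene_of[gene_id]])
            if u < f_enh:
                roles[gene_id] = "enhancer"
                log2fc[gene_id] = coupling * fc_acs + eps
            elif u < f_enh + f_rep:
                roles[gene_id] = "repressor"
                log2fc[gene_id] = -coupling * fc_acs + eps
            else:
                roles[gene_id] = "none"
                log2fc[gene_id] = eps
        else:
            roles[gene_id] = "none"
            log2fc[gene_id] = eps
    fdr = {g: (float(rng.uniform(0, 0.04)) if roles[g] != "none"
               else float(rng.uniform(0.05, 1.0)))
           for g in gene_table.index}
    table = pd.DataFrame({
        "log2fc": pd.Series(log2fc), "fdr": pd.Series(fdr),
    }).rename_axis("gene_id")
    if truth is not None:
        acs_of_gene = {g: a for a, g in links.items()}
        truth.gene_truth = {
            g: {"log2fc": float(table.loc[g, "log2fc"]), "role": roles[g],
                "acs_id": acs_of_gene.get(g)}
            for g in gene_table.index}
        truth.params.update({"role_design": list(role_design),
                             "coupling": coupling,
                             "expression_noise_sd": noise_sd})
    table.attrs["roles"] = roles
    return table


# ---------------------------------------------------------------------------
# whole-study convenience


def default_activities(n_motifs: int, n_active: int, activity_range=(0.3, 1.0),
                       seed: int = 0) -> np.ndarray:
    """Activity vector with ``n_active`` non-zero entries of alternating sign.

    Magnitudes are uniform in ``activity_range``; signs alternate so the
    study always contains both opening-site (activator-like) and
    closing-site (repressor-like, SCRT1-style) motifs.
    """
    rng = np.random.default_rng(seed)
    beta = np.zeros(n_motifs)
    which = rng.choice(n_motifs, size=n_active, replace=False)
    mags = rng.uniform(*activity_range, size=n_active)
    signs = np.array([1 if k % 2 == 0 else -1 for k in range(n_active)])
    beta[which] = mags * signs
    return beta


def simulate_study(n_acs: int = 2000, n_motifs: int = 50, n_active: int = 10,
                   activity_range=(0.3, 1.0), planting_prob: float = 0.1,
                   noise_sd: float = 0.25, n_per_group: int = 3,
                   dispersion: float = 0.2, mean_count: float = 100.0,
                   length_range=(250, 450), gc: float = 0.45,
                   width_range=(8, 14), ic_range=(1.1, 1.6),
                   role_design=(0.4, 0.2), expression_noise_sd: float = 0.2,
                   seed: int = 0) -> dict:
    """Generate a complete synthetic study for the full pipeline.

    Returns a dict with pwms, sequences, regions, counts, fragments,
    tss_table, gene_table, links and the consolidated truth.  The defaults
    give a 3-vs-3 design where roughly a fifth of the ACS change between
    conditions, echoing the scale of postnatal islet maturation data.
    """
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]
    pwms = sample_motif_collection(n_motifs, seeds[0], width_range, ic_range)
    beta = default_activities(n_motifs, n_active, activity_range, seeds[1])
    sequences, regions, truth = generate_acs_set(
        n_acs, length_range, gc, pwms, planting_prob, beta,
        noise_sd=noise_sd, seed=seeds[2])
    counts = simulate_counts(truth, n_per_group, seed=seeds[3],
                             dispersion=dispersion, mean_count=mean_count)
    fragments = simulate_fragments(regions, counts, seed=seeds[4])
    tss_table = make_tss_table(regions, seed=seeds[5])
    links = {r.id: f"gene_{i + 1:05d}" for i, r in enumerate(regions)}
    acs_fc = pd.Series(truth.acs_log2fc_true, index=truth.acs_ids)
    gene_table = simulate_expression(
        tss_table, links, acs_fc, role_design,
        noise_sd=expression_noise_sd, seed=seeds[5], truth=truth)
    truth.params.update({"n_motifs": n_motifs, "n_active": n_active,
                         "activity_range": list(activity_range),
                         "study_seed": seed})
    return {"pwms": pwms, "sequences": sequences, "regions": regions,
            "counts": counts, "fragments": fragments, "tss_table": tss_table,
            "gene_table": gene_table, "links": links, "truth": truth}
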