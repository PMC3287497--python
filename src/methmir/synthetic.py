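"""Synthetic genome bundle generator.

Emits a complete toy study — genome FASTA, GTF annotation, two single-base
methylome call sets (an embryonic-stem-like line "H1" and a fibroblast-like
line "IMR90"), miRNA target tables from two prediction sources, a
tissue-panel expression matrix with probe structure, RNA-seq-like RPKM
tables, orthologous 3'UTR alignments (pairwise FASTA for substitution rates,
3-species MAF for indel polarization) and cancer-gene labels — together with
the per-gene ground truth.

The generative model couples everything through a Gaussian copula over four
per-gene latents: promoter methylation propensity m* (uniform marginal),
miRNA target burden (negative-binomial counts), expression level, and 3'UTR
substitution rate. Latent correlations are calibrated by the rank-correlation
inversion r = 2 sin(pi * rho / 6) with a Monte-Carlo correction for the
discreteness of the count marginal, so the *population* Spearman couplings
equal the configured targets. Promoter CpG density (hence CpG O/E and CpG
islands) decreases in m*; DMRs (hypermethylated in IMR90) and PMDs (IMR90
domains at ~40% methylation) are planted over genes drawn from the
low-methylation stratum; cancer labels are drawn preferentially from
low-m*/high-burden genes. All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _ss

__all__ = ["SimulationConfig", "SyntheticBundle", "simulate",
           "draw_gene_features", "ground_truth_report", "evolve_sequence"]

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
A, C, G, T = 0, 1, 2, 3


@dataclass
class SimulationConfig:
    n_genes: int = 5000
    n_chromosomes: int = 4
    seed: int = 0

    # population Spearman couplings
    rho_meth_targets: float = -0.29
    rho_meth_expression: float = -0.47
    rho_targets_expression: float = 0.20
    rho_cpgoe_expression_germline: float = 0.37
    k3u_meth_rho: float = 0.15

    # target-count marginals
    nb_mean: float = 15.0
    nb_size: float = 4.0
    pictar_mean: float = 8.0
    pictar_size: float = 3.0
    pictar_latent_corr: float = 0.9
    n_mirnas: int = 300

    # 3'UTR length model: UL = ul_base + ul_per_site * Nt + noise
    ul_base: float = 120.0
    ul_per_site: float = 28.0
    ul_noise_sd: float = 100.0
    ul_min: int = 60
    ul_max: int = 4000

    # planted regions
    dmr_count: int = 20
    dmr_meth: float = 0.9
    dmr_flank: int = 400
    pmd_count: int = 5
    pmd_mean_meth: float = 0.40
    pmd_length: int = 100_000

    # methylome
    coverage_mean: float = 12.0
    background_meth: float = 0.95
    background_cpg_rate: float = 0.04
    meth_read_prob: float = 0.97
    bisulfite_error: float = 0.01
    n_chh_sites: int = 2000

    # promoter sequence model
    promoter_cpg_slot_min: float = 0.02
    promoter_cpg_slot_span: float = 0.12
    promoter_gc_base: float = 0.38
    promoter_gc_span: float = 0.25

    # layout: spacers keep each locus >= one PMD window so at most one
    # promoter can dominate any 10 kb window
    spacer_min: int = 8300
    spacer_max: int = 9000

    # annotation perturbations
    multi_transcript_fraction: float = 0.25
    distant_tss_fraction: float = 0.03
    ambiguous_utr_fraction: float = 0.02

    # expression panels
    n_germline_tissues: int = 16
    n_somatic_tissues: int = 24
    ad_log_mean: float = 5.3
    ad_log_sd: float = 1.1
    extra_probe_fraction: float = 0.3
    low_conf_probe_fraction: float = 0.1
    rpkm_cell_corr: float = 0.9

    # evolution
    k3u_min: float = 0.05
    k3u_span: float = 0.25
    kappa: float = 2.0
    chimp_k: float = 0.02
    macaque_k: float = 0.06
    indel_rate_per_base: float = 0.01

    # cancer labels
    cancer_fraction: float = 0.04
    dominant_recessive_ratio: float = 4.0
    n_ambiguous_cancer: int = 5

    def validate(self):
        for name in ("rho_meth_targets", "rho_meth_expression",
                     "rho_targets_expression",
                     "rho_cpgoe_expression_germline", "k3u_meth_rho"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (-1, 1)")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticBundle:
    out_dir: Path
    paths: dict[str, Path]
    truth: pd.DataFrame
    dmr_truth: pd.DataFrame
    pmd_truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def _latent_r(rho: float) -> float:
    """Pearson latent correlation giving Spearman ``rho`` between the
    Gaussian-copula transforms of two continuous marginals."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def _nb_ppf(u: np.ndarray, mean: float, size: float) -> np.ndarray:
    p = size / (size + mean)
    return _ss.nbinom.ppf(u, size, p).astype(np.int64)


def _count_attenuation(mean: float, size: float, seed: int,
                       n_mc: int = 40000) -> float:
    """Monte-Carlo attenuation of Spearman correlation induced by mapping a
    Gaussian latent through a discrete NB quantile transform."""
    rng = np.random.default_rng(seed)
    r0 = 0.7
    z = rng.standard_normal((n_mc, 2))
    u = z[:, 0]
    v = r0 * z[:, 0] + np.sqrt(1 - r0 ** 2) * z[:, 1]
    counts = _nb_ppf(_ss.norm.cdf(v), mean, size)
    realized, _ = _ss.spearmanr(u, counts)
    continuous = 6.0 / np.pi * np.arcsin(r0 / 2.0)
    return float(realized / continuous)


def _calibrated_r(rho_target: float, attenuation: float) -> float:
    needed = rho_target / attenuation
    if abs(needed) >= 1.0:
        raise ValueError(
            f"infeasible copula calibration: |rho|={abs(rho_target):.3f} "
            f"exceeds the achievable bound {attenuation:.3f} for this count "
            "marginal")
    return _latent_r(needed)


def draw_gene_features(config: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-gene latent table (no genome yet).

    Columns: m_star, z_expr, z_k3u, Nt, Np, UL, k3u_true, cds_length,
    strand, plus annotation-perturbation flags.
    """
    config.validate()
    n = config.n_genes
    att = _count_attenuation(config.nb_mean, config.nb_size,
                             seed=config.seed + 101)
    r_mn = _calibrated_r(config.rho_meth_targets, att)
    r_ne = _calibrated_r(config.rho_targets_expression, att)
    r_me = _latent_r(config.rho_meth_expression)
    r_mk = _latent_r(config.k3u_meth_rho)
    corr = np.array([
        [1.0, r_mn, r_me, r_mk],   # m
        [r_mn, 1.0, r_ne, 0.0],    # target burden
        [r_me, r_ne, 1.0, 0.0],    # expression
        [r_mk, 0.0, 0.0, 1.0],     # 3'UTR substitution rate
    ])
    w, _ = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise ValueError("coupling targets yield a non-PSD latent correlation")
    L = np.linalg.cholesky(corr + np.eye(4) * max(0.0, 1e-12 - w.min()))
    z = rng.standard_normal((n, 4)) @ L.T
    m_star = _ss.norm.cdf(z[:, 0])
    nt = _nb_ppf(_ss.norm.cdf(z[:, 1]), config.nb_mean, config.nb_size)
    c = config.pictar_latent_corr
    z_np = c * z[:, 1] + np.sqrt(1 - c ** 2) * rng.standard_normal(n)
    np_counts = _nb_ppf(_ss.norm.cdf(z_np), config.pictar_mean,
                        config.pictar_size)
    ul = np.clip(np.round(config.ul_base + config.ul_per_site * nt
                          + rng.normal(0, config.ul_noise_sd, n)),
                 config.ul_min, config.ul_max).astype(np.int64)
    k3u_true = config.k3u_min + config.k3u_span * _ss.norm.cdf(z[:, 3])
    cds_length = 3 * rng.integers(100, 500, n)
    strand = np.where(rng.random(n) < 0.7, "+", "-")

    multi = rng.random(n) < config.multi_transcript_fraction
    distant = multi & (rng.random(n) < config.distant_tss_fraction
                       / max(config.multi_transcript_fraction, 1e-9))
    ambiguous = multi & ~distant & (
        rng.random(n) < config.ambiguous_utr_fraction
        / max(config.multi_transcript_fraction, 1e-9))

    df = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n)],
        "m_star": m_star,
        "z_expr": z[:, 2],
        "z_k3u": z[:, 3],
        "Nt_true": nt,
        "Np_true": np_counts,
        "UL_true": ul,
        "k3u_true": k3u_true,
        "cds_length": cds_length,
        "strand": strand,
        "multi_transcript": multi,
        "distant_tss": distant,
        "ambiguous_utr": ambiguous,
    })
    return df


def evolve_sequence(codes: np.ndarray, k: float, kappa: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded (0..3 = ACGT) sequence under Kimura's two-parameter
    process to total divergence ``k`` substitutions/site with
    transition/transversion rate ratio ``kappa``."""
    bt = k / (kappa + 2.0)
    at = kappa * bt
    e4b = np.exp(-4.0 * bt)
    e2ab = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.5 - 0.5 * e4b  # split evenly between the two partners
    u = rng.random(codes.size)
    ts_map = np.array([G, T, A, C], dtype=np.uint8)       # A<->G, C<->T
    tv1_map = np.array([C, A, C, A], dtype=np.uint8)
    tv2_map = np.array([T, G, T, G], dtype=np.uint8)
    out = codes.copy()
    sel = u < p_ts
    out[sel] = ts_map[codes[sel]]
    sel = (u >= p_ts) & (u < p_ts + p_tv / 2)
    out[sel] = tv1_map[codes[sel]]
    sel = (u >= p_ts + p_tv / 2) & (u < p_ts + p_tv)
    out[sel] = tv2_map[codes[sel]]
    return out


def _revcomp(codes: np.ndarray) -> np.ndarray:
    comp = np.array([T, G, C, A], dtype=np.uint8)
    return comp[codes[::-1]]


def _codes_to_str(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode()


def _write_fasta(path: Path, records: list[tuple[str, np.ndarray]],
                 width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, codes in records:
            fh.write(f">{name}\n")
            s = _LETTERS[codes].tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _layout(config: SimulationConfig, features: pd.DataFrame,
            rng: np.random.Generator) -> pd.DataFrame:
    """Assign each gene slot genomic coordinates on round-robin chromosome
    blocks. Returns features with coordinate columns appended."""
    n = config.n_genes
    per_chrom = np.array_split(np.arange(n), config.n_chromosomes)
    cols = {k: np.zeros(n, dtype=np.int64) for k in
            ("tss", "tx_start", "tx_end", "cds_start", "cds_end",
             "utr3_start", "utr3_end", "prom_start", "prom_end")}
    chrom = np.empty(n, dtype=object)
    for ci, idxs in enumerate(per_chrom):
        name = f"chr{ci + 1}"
        cursor = 2000
        for i in idxs:
            cursor += int(rng.integers(config.spacer_min, config.spacer_max))
            ul = int(features.at[i, "UL_true"])
            cds = int(features.at[i, "cds_length"])
            if features.at[i, "strand"] == "+":
                tss = cursor + 1000
                tx_start = tss
                cds_start = tss + 200
                cds_end = cds_start + cds
                utr3_start = cds_end
                utr3_end = utr3_start + ul
                tx_end = utr3_end
                prom_start, prom_end = tss - 1000, tss + 200
            else:
                tx_start = cursor
                utr3_start = tx_start
                utr3_end = utr3_start + ul
                cds_start = utr3_end
                cds_end = cds_start + cds
                tx_end = cds_end + 200
                tss = tx_end - 1
                prom_start, prom_end = tss - 200, tss + 1000
            chrom[i] = name
            for k, v in (("tss", tss), ("tx_start", tx_start),
                         ("tx_end", tx_end), ("cds_start", cds_start),
                         ("cds_end", cds_end), ("utr3_start", utr3_start),
                         ("utr3_end", utr3_end), ("prom_start", prom_start),
                         ("prom_end", prom_end)):
                cols[k][i] = v
            cursor = max(tx_end, prom_end)
    out = features.copy()
    out["chrom"] = chrom
    for k, v in cols.items():
        out[k] = v
    return out


def _reserve_region_slots(config: SimulationConfig, features: pd.DataFrame,
                          rng: np.random.Generator):
    """Pick consecutive slot runs for PMDs and isolated slots for DMRs, and
    swap latent rows so those slots carry low-methylation genes."""
    n = config.n_genes
    per_chrom = np.array_split(np.arange(n), config.n_chromosomes)
    avg_locus = (config.spacer_min + config.spacer_max) / 2 + 1200 + 200 \
        + 900 + float(features["UL_true"].mean())
    run_len = max(3, int(round(config.pmd_length / avg_locus)))

    pmd_runs: list[np.ndarray] = []
    used = np.zeros(n, dtype=bool)
    ci = 0
    for _ in range(config.pmd_count):
        for _attempt in range(200):
            idxs = per_chrom[ci % config.n_chromosomes]
            if idxs.size <= run_len + 2:
                ci += 1
                continue
            start = int(rng.integers(1, idxs.size - run_len - 1))
            run = idxs[start:start + run_len]
            if not used[run].any():
                pmd_runs.append(run)
                used[run] = True
                used[max(run[0] - 1, 0)] = True
                used[min(run[-1] + 1, n - 1)] = True
                break
        ci += 1

    eligible = np.flatnonzero(~used & ~features["distant_tss"].to_numpy()
                              & ~features["ambiguous_utr"].to_numpy())
    dmr_slots = rng.choice(eligible, size=config.dmr_count, replace=False)
    used[dmr_slots] = True

    # swap rows so reserved slots carry low-m* genes
    def _fill(slots: np.ndarray, m_cut: float):
        pool = np.flatnonzero((features["m_star"].to_numpy() < m_cut) & ~used)
        pool = rng.permutation(pool)
        pi = 0
        for s in slots:
            if features.at[s, "m_star"] >= m_cut:
                while pi < pool.size and features.at[pool[pi], "m_star"] >= m_cut:
                    pi += 1
                if pi >= pool.size:
                    break
                j = pool[pi]
                pi += 1
                fa, fb = features.iloc[s].copy(), features.iloc[j].copy()
                ga, gb = fa["gene_id"], fb["gene_id"]
                features.iloc[s], features.iloc[j] = fb, fa
                # keep gene_id tied to the slot so ids stay positional
                features.at[s, "gene_id"] = ga
                features.at[j, "gene_id"] = gb

    all_pmd = np.concatenate(pmd_runs) if pmd_runs else np.zeros(0, int)
    _fill(all_pmd, 0.35)
    _fill(np.asarray(dmr_slots), 0.40)
    # reserved slots must survive the annotation filters
    keep = np.concatenate([all_pmd, np.asarray(dmr_slots)])
    features.loc[keep, ["distant_tss", "ambiguous_utr"]] = False
    return pmd_runs, np.sort(np.asarray(dmr_slots))


def _build_genome(config: SimulationConfig, feats: pd.DataFrame,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    genomes: dict[str, np.ndarray] = {}
    for chrom, sub in feats.groupby("chrom", sort=True):
        length = int(max(sub["tx_end"].max(), sub["prom_end"].max())) + 3000
        codes = rng.choice(np.arange(4, dtype=np.uint8), size=length,
                           p=[0.3, 0.2, 0.2, 0.3])
        # thin background CpGs to the configured rate (raw rate 0.04)
        cg = np.flatnonzero((codes[:-1] == C) & (codes[1:] == G))
        kill = cg[rng.random(cg.size) >= config.background_cpg_rate / 0.04]
        codes[kill + 1] = A
        for _, g in sub.iterrows():
            s, e = int(g["prom_start"]), int(g["prom_end"])
            m = float(g["m_star"])
            gc = config.promoter_gc_base + config.promoter_gc_span * (1 - m)
            pl = e - s
            prom = rng.choice(np.arange(4, dtype=np.uint8), size=pl,
                              p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            pcg = np.flatnonzero((prom[:-1] == C) & (prom[1:] == G))
            prom[pcg + 1] = A
            slot_p = config.promoter_cpg_slot_min \
                + config.promoter_cpg_slot_span * (1 - m)
            slots = np.arange(0, pl - 1, 2)
            chosen = slots[rng.random(slots.size) < slot_p]
            prom[chosen] = C
            prom[chosen + 1] = G
            codes[s:e] = prom
        genomes[chrom] = codes
    return genomes


def _methylome_calls(config, feats, genomes, pmd_truth, dmr_truth, rng):
    """Per cell line call DataFrames; planted PMD/DMR overrides hit IMR90."""
    frames = {"H1": [], "IMR90": []}
    for chrom in sorted(genomes):
        codes = genomes[chrom]
        cpg = np.flatnonzero((codes[:-1] == C) & (codes[1:] == G))
        p_a = np.full(cpg.size, config.background_meth)
        sub = feats[feats["chrom"] == chrom]
        for _, g in sub.iterrows():
            i, j = np.searchsorted(cpg, [int(g["prom_start"]),
                                         int(g["prom_end"])])
            p_a[i:j] = float(g["m_star"])
        p_b = p_a.copy()
        for _, r in pmd_truth[pmd_truth["chrom"] == chrom].iterrows():
            i, j = np.searchsorted(cpg, [int(r["start"]), int(r["end"])])
            p_b[i:j] = config.pmd_mean_meth
        m_by_gene = dict(zip(feats["gene_id"], feats["m_star"]))
        for _, r in dmr_truth[dmr_truth["chrom"] == chrom].iterrows():
            i, j = np.searchsorted(cpg, [int(r["start"]), int(r["end"])])
            # a planted DMR is a coherent block: hypomethylated at the
            # gene's level in the reference line, hypermethylated in the
            # second line across the whole interval (flanks included)
            p_a[i:j] = m_by_gene[r["gene_id"]]
            p_b[i:j] = config.dmr_meth

        # a sprinkling of non-CpG (CHH) cytosines exercises context filters
        c_pos = np.flatnonzero(codes[:-1] == C)
        non_cpg = np.setdiff1d(c_pos, cpg)
        n_chh = min(config.n_chh_sites // len(genomes), non_cpg.size)
        chh = np.sort(rng.choice(non_cpg, size=n_chh, replace=False))

        for cell, p_true in (("H1", p_a), ("IMR90", p_b)):
            state = rng.random(cpg.size) < p_true
            total = 1 + rng.poisson(config.coverage_mean - 1, cpg.size)
            prob = np.where(state, config.meth_read_prob,
                            config.bisulfite_error)
            mc = rng.binomial(total, prob)
            frames[cell].append(pd.DataFrame({
                "chrom": chrom, "pos": cpg, "strand": "+", "context": "CG",
                "mc_reads": mc, "total_reads": total}))
            chh_total = 1 + rng.poisson(config.coverage_mean - 1, chh.size)
            chh_mc = rng.binomial(chh_total, 0.02)
            frames[cell].append(pd.DataFrame({
                "chrom": chrom, "pos": chh, "strand": "+", "context": "CHH",
                "mc_reads": chh_mc, "total_reads": chh_total}))
    out = {}
    for cell, fl in frames.items():
        df = pd.concat(fl, ignore_index=True)
        out[cell] = df.sort_values(["chrom", "pos"],
                                   kind="mergesort").reset_index(drop=True)
    return out


def _write_gtf(path: Path, feats: pd.DataFrame, rng: np.random.Generator):
    lines = []
    for _, g in feats.iterrows():
        gid = g["gene_id"]
        chrom, strand = g["chrom"], g["strand"]

        def feat(feature, s0, e0, tid):
            lines.append((chrom, int(s0),
                          f"{chrom}\tsim\t{feature}\t{s0 + 1}\t{e0}\t.\t"
                          f"{strand}\t.\tgene_id \"{gid}\"; "
                          f"transcript_id \"{tid}\";"))

        feat("transcript", g["tx_start"], g["tx_end"], f"{gid}.t1")
        feat("CDS", g["cds_start"], g["cds_end"], f"{gid}.t1")
        feat("three_prime_utr", g["utr3_start"], g["utr3_end"], f"{gid}.t1")

        if g["multi_transcript"]:
            if g["distant_tss"]:
                delta = int(rng.integers(250, 600))
            else:
                delta = int(rng.integers(10, 150))
            cds2 = max(60, int(g["cds_length"]) - 150)
            u3s, u3e = int(g["utr3_start"]), int(g["utr3_end"])
            if g["ambiguous_utr"]:
                shift = (u3e - u3s) + 10
                u3s, u3e = u3s + shift, u3e + shift
            if strand == "+":
                tss2 = int(g["tss"]) + delta
                tx2 = (tss2, max(int(g["tx_end"]), u3e))
                cds2_iv = (tss2 + 200, tss2 + 200 + cds2)
            else:
                tss2 = int(g["tss"]) - delta
                tx2 = (min(int(g["tx_start"]), u3s), tss2 + 1)
                cds2_iv = (tss2 - 200 - cds2 + 1, tss2 - 200 + 1)
            feat("transcript", tx2[0], tx2[1], f"{gid}.t2")
            feat("CDS", cds2_iv[0], cds2_iv[1], f"{gid}.t2")
            feat("three_prime_utr", u3s, u3e, f"{gid}.t2")
    lines.sort(key=lambda x: (x[0], x[1]))
    with open(path, "w") as fh:
        for _, _, ln in lines:
            fh.write(ln + "\n")


def _target_tables(config, feats, rng) -> pd.DataFrame:
    rows = []
    for source, col in (("mirtarget2", "Nt_true"), ("pictar", "Np_true")):
        for _, g in feats.iterrows():
            n = int(g[col])
            if n == 0:
                continue
            ul = int(g["UL_true"])
            pos = np.sort(rng.choice(ul, size=min(n, ul), replace=False))
            mirs = rng.integers(1, config.n_mirnas + 1, size=pos.size)
            for mi, p in zip(mirs, pos):
                rows.append((g["gene_id"], f"mir-{mi}", source, int(p)))
    df = pd.DataFrame(rows, columns=["gene_id", "mirna_id", "source",
                                     "position"])
    # exact duplicate records: downstream counting must deduplicate
    dup = df.iloc[::97].copy()
    return pd.concat([df, dup], ignore_index=True)


def _tissue_loading(config: SimulationConfig, n_mc: int = 20000) -> float:
    """Per-germline-tissue latent loading r such that Spearman between the
    anti-methylation latent and the *mean intensity* over the germline panel
    hits the configured target."""
    target = config.rho_cpgoe_expression_germline
    n_g = config.n_germline_tissues
    big_r = _latent_r(target)
    r = float(np.sqrt(big_r ** 2 / (n_g * (1 - big_r ** 2) + big_r ** 2)))
    rng = np.random.default_rng(config.seed + 202)
    w = rng.standard_normal(n_mc)
    eps = rng.standard_normal((n_mc, n_g))
    for _ in range(3):
        lat = r * w[:, None] + np.sqrt(1 - r ** 2) * eps
        mean_ad = np.exp(config.ad_log_mean + config.ad_log_sd * lat
                         ).mean(axis=1)
        realized, _ = _ss.spearmanr(w, mean_ad)
        r = float(np.clip(r * target / realized, 1e-4, 0.99))
    return r


def _expression_tables(config, feats, rng):
    n = config.n_genes
    w = -_ss.norm.ppf(feats["m_star"].to_numpy())  # anti-methylation latent
    n_g, n_s = config.n_germline_tissues, config.n_somatic_tissues
    samples, classes, cols = [], {}, []
    # the configured germline coupling is for *mean* germline expression;
    # averaging n_g tissues concentrates the shared signal while the
    # heavy-tailed intensity scale re-weights tissues, so the per-tissue
    # loading is calibrated by Monte Carlo against the measured quantity
    r_tissue = _tissue_loading(config)
    for t in range(n_g):
        name = f"germ_{t + 1:02d}"
        r = r_tissue + rng.normal(0, 0.01)
        lat = r * w + np.sqrt(max(1 - r ** 2, 0)) * rng.standard_normal(n)
        samples.append(name)
        classes[name] = "germline"
        cols.append(lat)
    for t in range(n_s):
        name = f"soma_{t + 1:02d}"
        r = rng.normal(0, 0.03)
        lat = r * w + np.sqrt(max(1 - r ** 2, 0)) * rng.standard_normal(n)
        samples.append(name)
        classes[name] = "somatic"
        cols.append(lat)
    lat = np.column_stack(cols)
    ad = np.round(np.exp(config.ad_log_mean + config.ad_log_sd * lat), 1)
    gene_ids = feats["gene_id"].to_numpy()

    probe_rows, probe_map = [], []
    for i, gid in enumerate(gene_ids):
        pid = f"pr{i:05d}_at"
        probe_rows.append((pid, ad[i]))
        probe_map.append((pid, gid))
        if rng.random() < config.extra_probe_fraction:
            noise = np.exp(rng.normal(0, 0.1, ad.shape[1]))
            if rng.random() < config.low_conf_probe_fraction:
                pid2 = f"pr{i:05d}_s_at"
                vals = np.round(ad[i] * noise * 10, 1)  # wild: must be dropped
            else:
                pid2 = f"pr{i:05d}b_at"
                vals = np.round(ad[i] * noise, 1)
            probe_rows.append((pid2, vals))
            probe_map.append((pid2, gid))
    probe_matrix = pd.DataFrame(
        {pid: vals for pid, vals in probe_rows}, index=samples).T
    probe_matrix.index.name = "probe_id"
    probe_map_df = pd.DataFrame(probe_map, columns=["probe_id", "gene_id"])
    classes_df = pd.DataFrame(sorted(classes.items()),
                              columns=["sample", "tissue_class"])

    z_e = feats["z_expr"].to_numpy()
    rpkm = {}
    rpkm["H1"] = np.round(np.exp(1.0 + 1.2 * z_e), 4)
    cc = config.rpkm_cell_corr
    z2 = cc * z_e + np.sqrt(1 - cc ** 2) * rng.standard_normal(n)
    rpkm["IMR90"] = np.round(np.exp(1.0 + 1.2 * z2), 4)
    rpkm_dfs = {cell: pd.DataFrame({"gene_id": gene_ids, "rpkm": v})
                for cell, v in rpkm.items()}
    return probe_matrix, probe_map_df, classes_df, rpkm_dfs


def _ortholog_alignments(config, feats, genomes, rng, pair_path, maf_path):
    pair_records = []
    ins_rates, del_rates = [], []
    with open(maf_path, "w") as maf:
        maf.write("##maf version=1\n")
        for _, g in feats.iterrows():
            codes = genomes[g["chrom"]][int(g["utr3_start"]):
                                        int(g["utr3_end"])]
            if g["strand"] == "-":
                codes = _revcomp(codes)
            mouse = evolve_sequence(codes, float(g["k3u_true"]),
                                    config.kappa, rng)
            pair_records.append((f"{g['gene_id']}|human", codes))
            pair_records.append((f"{g['gene_id']}|mouse", mouse))

            chimp = evolve_sequence(codes, config.chimp_k, config.kappa, rng)
            mac = evolve_sequence(codes, config.macaque_k, config.kappa, rng)
            h = list(_codes_to_str(codes))
            c_ = list(_codes_to_str(chimp))
            m_ = list(_codes_to_str(mac))
            n_events = rng.poisson(config.indel_rate_per_base * len(h) / 3)
            for _e in range(n_events):
                ln = 1 + int(rng.geometric(0.5))
                at = int(rng.integers(0, max(len(h) - ln, 1)))
                if rng.random() < 0.5:  # human-specific deletion
                    for q in range(at, min(at + ln, len(h))):
                        h[q] = "-"
                else:                   # human-specific insertion
                    ins = _codes_to_str(
                        rng.integers(0, 4, ln).astype(np.uint8))
                    for off, ch in enumerate(ins):
                        h.insert(at + off, ch)
                        c_.insert(at + off, "-")
                        m_.insert(at + off, "-")
            hs, cs, ms = "".join(h), "".join(c_), "".join(m_)
            cols = len(hs)
            gid = g["gene_id"]
            maf.write("a score=0.0\n")
            for sp, seq in (("human", hs), ("chimp", cs), ("macaque", ms)):
                maf.write(f"s {sp}.{gid} 0 {len(seq.replace('-', ''))} + "
                          f"{len(seq.replace('-', ''))} {seq}\n")
            maf.write("\n")
            # unanimity-polarized true rates (what the alignment implies)
            ins_cols = sum(1 for x, a, b in zip(hs, cs, ms)
                           if x != "-" and a == "-" and b == "-")
            del_cols = sum(1 for x, a, b in zip(hs, cs, ms)
                           if x == "-" and a != "-" and b != "-")
            ins_rates.append(ins_cols / cols)
            del_rates.append(del_cols / cols)
    _write_fasta(pair_path, pair_records)
    return np.array(ins_rates), np.array(del_rates)


def _cancer_labels(config, feats, rng) -> pd.DataFrame:
    n = config.n_genes
    n_cancer = max(2, int(round(config.cancer_fraction * n)))
    m_rank = _ss.rankdata(feats["m_star"]) / n
    t_rank = _ss.rankdata(feats["Nt_true"]) / n
    w = np.exp(1.5 * (t_rank - m_rank))
    chosen = rng.choice(n, size=n_cancer, replace=False, p=w / w.sum())
    ratio = config.dominant_recessive_ratio
    n_amb = min(config.n_ambiguous_cancer, max(n_cancer - 2, 0))
    rest = rng.permutation(chosen)
    amb = rest[:n_amb]
    rest = rest[n_amb:]
    n_rec = max(1, int(round(rest.size / (ratio + 1.0))))
    # recessive genes drawn from the lowest-methylation (CGI-rich) stratum
    order = np.argsort(feats["m_star"].to_numpy()[rest], kind="mergesort")
    rec = rest[order[:n_rec]]
    dom = np.setdiff1d(rest, rec)
    rows = [(feats.at[i, "gene_id"], "dominant") for i in dom]
    rows += [(feats.at[i, "gene_id"], "recessive") for i in rec]
    rows += [(feats.at[i, "gene_id"], "ambiguous") for i in amb]
    rows.sort()
    return pd.DataFrame(rows, columns=["gene_id", "cancer_label"])


def simulate(config: SimulationConfig, out_dir) -> SyntheticBundle:
    """Generate the full bundle under ``out_dir`` and return handles plus
    ground truth. Deterministic given the config (including its seed)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    feats = draw_gene_features(config, rng)
    pmd_runs, dmr_slots = _reserve_region_slots(config, feats, rng)
    feats = _layout(config, feats, rng)

    pmd_rows = []
    for run in pmd_runs:
        first = feats.iloc[run[0]]
        chrom = first["chrom"]
        start = max(int(first["prom_start"]) - 2000, 0)
        pmd_rows.append((chrom, start, start + config.pmd_length))
    pmd_truth = pd.DataFrame(pmd_rows, columns=["chrom", "start", "end"])
    dmr_rows = []
    for s in dmr_slots:
        g = feats.iloc[s]
        dmr_rows.append((g["chrom"],
                         max(int(g["prom_start"]) - config.dmr_flank, 0),
                         int(g["prom_end"]) + config.dmr_flank, g["gene_id"]))
    dmr_truth = pd.DataFrame(dmr_rows,
                             columns=["chrom", "start", "end", "gene_id"])

    genomes = _build_genome(config, feats, rng)
    calls = _methylome_calls(config, feats, genomes, pmd_truth, dmr_truth,
                             rng)

    paths = {
        "genome": out / "genome.fa",
        "gtf": out / "annotation.gtf",
        "calls_H1": out / "calls_H1.tsv",
        "calls_IMR90": out / "calls_IMR90.tsv",
        "targets": out / "targets.tsv",
        "expression": out / "expression_probes.tsv",
        "probe_map": out / "probe_map.tsv",
        "tissue_classes": out / "tissue_classes.tsv",
        "rpkm_H1": out / "rpkm_H1.tsv",
        "rpkm_IMR90": out / "rpkm_IMR90.tsv",
        "utr3_pairs": out / "utr3_pairs.fa",
        "utr3_maf": out / "utr3_alignments.maf",
        "cancer_labels": out / "cancer_labels.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "dmr_truth": out / "truth_dmrs.tsv",
        "pmd_truth": out / "truth_pmds.tsv",
        "config": out / "config.txt",
    }

    _write_fasta(paths["genome"],
                 [(chrom, genomes[chrom]) for chrom in sorted(genomes)])
    _write_gtf(paths["gtf"], feats, rng)
    for cell in ("H1", "IMR90"):
        calls[cell].to_csv(paths[f"calls_{cell}"], sep="\t", index=False,
                           header=False)
    targets = _target_tables(config, feats, rng)
    targets.to_csv(paths["targets"], sep="\t", index=False)
    probe_matrix, probe_map, classes_df, rpkm_dfs = _expression_tables(
        config, feats, rng)
    probe_matrix.to_csv(paths["expression"], sep="\t")
    probe_map.to_csv(paths["probe_map"], sep="\t", index=False)
    classes_df.to_csv(paths["tissue_classes"], sep="\t", index=False)
    for cell, df in rpkm_dfs.items():
        df.to_csv(paths[f"rpkm_{cell}"], sep="\t", index=False)
    ins_rates, del_rates = _ortholog_alignments(
        config, feats, genomes, rng, paths["utr3_pairs"], paths["utr3_maf"])
    cancer = _cancer_labels(config, feats, rng)
    cancer.to_csv(paths["cancer_labels"], sep="\t", index=False)

    truth = feats.copy()
    truth["insertion_rate_true"] = ins_rates
    truth["deletion_rate_true"] = del_rates
    truth["in_dmr_true"] = False
    truth.loc[dmr_slots, "in_dmr_true"] = True
    truth["in_pmd_true"] = False
    for run in pmd_runs:
        truth.loc[run, "in_pmd_true"] = True
    truth = truth.merge(cancer, on="gene_id", how="left")
    truth["cancer_label"] = truth["cancer_label"].fillna("none")
    truth["retained_expected"] = ~(truth["distant_tss"]
                                   | truth["ambiguous_utr"])
    truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    dmr_truth.to_csv(paths["dmr_truth"], sep="\t", index=False)
    pmd_truth.to_csv(paths["pmd_truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        for k, v in asdict(config).items():
            fh.write(f"{k}={v}\n")

    return SyntheticBundle(out, paths, truth, dmr_truth, pmd_truth, config)


def ground_truth_report(bundle: SyntheticBundle) -> pd.DataFrame:
    """Per-gene true latents and planted-region memberships."""
    return pd.read_csv(bundle.paths["ground_truth"], sep="\t")
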