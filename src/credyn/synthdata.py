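"""Seeded synthetic multi-omics bundles with planted temporal structure.

The generator lays out a small genome of gene "slots" and emits every input
the pipeline consumes: gene models, enhancer/promoter catalogs (plus decoy
enhancers that must be filtered out), a blacklist, per-assay fragment sets
for the three damage timepoints, peak calls derived from planted binary
states, TF footprint tables with planted high-variance TFs, DE tables,
chromatin loops covering planted enhancer-gene pairs, and p53 peaks.

Planted temporal profiles emulate the study's qualitative patterns: distal
enhancer signal drops at moderate damage and rebounds at severe damage
(down-then-up), while promoter RNA and accessibility decline monotonically.
Fragment counts are negative-binomial (Gamma-Poisson) so recovery tests face
realistic overdispersion; peaks are derived from the planted states with
boundary jitter as the only state noise.  Every file is byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TIMEPOINTS = ("0h", "8h", "16h")

# slot geometry (bp): each gene occupies one 12 kb slot; element positions
# are fixed offsets chosen so that planted enhancers survive curation and
# no two elements (or their jittered peaks) can ever touch
SLOT = 12_000
_DISTAL_UPSTREAM = (5000, 4200, 3400)  # midpoint distances from the TSS
_PROXIMAL_UPSTREAM = 1500
_ENH_LEN = 400
_PROM_HALF = 500
_GENE_LEN = 3000

__all__ = ["SynthConfig", "SynthTruth", "generate_bundle", "truth_report", "load_truth"]


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    seed: int = 0
    n_genes: int = 800
    n_distal: int = 900
    n_proximal: int = 300
    n_promoters: int = 800
    n_decoy: int = 20
    # multiplicative temporal profiles (0h, 8h, 16h) per element class/assay
    class_profiles: dict = field(
        default_factory=lambda: {
            ("distal", "RNA"): (1.0, 0.6, 1.2),
            ("proximal", "RNA"): (1.0, 0.75, 0.55),
            ("promoter", "RNA"): (1.0, 0.7, 0.5),
            ("distal", "ATAC"): (1.0, 0.7, 1.1),
            ("proximal", "ATAC"): (1.0, 0.7, 1.1),
            ("promoter", "ATAC"): (1.0, 0.8, 0.65),
            ("distal", "H3K27ac"): (1.0, 0.6, 1.2),
            ("proximal", "H3K27ac"): (1.0, 0.6, 1.2),
            ("promoter", "H3K27ac"): (1.0, 0.6, 1.2),
        }
    )
    baseline_rate: float = 50.0  # expected fragments per element at 0 h
    dispersion: float = 0.05  # NB overdispersion (var = mu + dispersion * mu^2)
    frac_silent: float = 0.2  # elements with zero RNA at every timepoint
    background_rate: float = 0.02  # coverage fraction at state-negative timepoints
    # planted coordinated enhancer-gene pairs and non-coordinated distractors
    n_coordinated_pairs: int = 40
    n_distractor_pairs: int = 60
    pair_baseline_rate: float = 300.0
    pair_profile_down: tuple = (1.0, 0.45, 0.15)
    pair_profile_up: tuple = (0.15, 0.45, 1.0)
    gene_noise_sigma: float = 0.05  # lognormal sigma on gene TPM triples
    # footprint table shape
    n_tf: int = 60
    n_hi_var_tf: int = 8
    footprints_per_tf: int = 4  # per timepoint, per element class
    # state planting for ATAC / H3K27ac
    p_consistent_positive: float = 0.7
    p_consistent_negative: float = 0.15
    peak_jitter: float = 0.1  # boundary jitter as fraction of element length
    p53_bound_frac: float = 0.3
    fragment_length: int = 100
    library_size: int = 1_000_000  # total mapped fragments per sample (the
    # emitted files list only the element-proximal subset; the remainder is
    # genome-wide background that region counting would never touch)
    n_background_peaks: int = 500  # ATAC peaks away from any element
    n_de_extra: int = 50  # consistently-DE genes outside planted pairs

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_silent <= 1.0):
            raise ValueError("frac_silent must lie in [0, 1]")
        if self.n_distal > 3 * self.n_genes:
            raise ValueError("at most 3 distal enhancers per gene slot")
        if self.n_proximal > self.n_genes or self.n_promoters > self.n_genes:
            raise ValueError("at most one proximal enhancer / promoter per gene slot")
        for key, prof in self.class_profiles.items():
            if any(v <= 0 for v in prof):
                raise ValueError(f"profile {key} must be strictly positive")

    def chrom_sizes(self) -> dict[str, int]:
        """Genome layout: slots split 50/30/20% across three chromosomes."""
        n1 = self.n_genes // 2
        n2 = (3 * self.n_genes) // 10
        n3 = self.n_genes - n1 - n2
        return {
            "chr1": n1 * SLOT + 20_000,
            "chr2": n2 * SLOT + 20_000,
            "chr3": n3 * SLOT + 20_000,
        }


@dataclass
class SynthTruth:
    """Ground-truth ledger for a generated bundle."""

    elements: pd.DataFrame  # id, class, subclass, kept, removal_reason, states, rna counts
    pairs: pd.DataFrame  # enhancer_id, gene_id, planted {coordinated, distractor}, direction
    hi_var_tfs: list[str]
    p53_bound: set[str]


def _slot_coords(config: SynthConfig) -> list[tuple[str, int, str]]:
    """(chrom, slot_start, strand) per gene slot; strand alternates."""
    sizes = config.chrom_sizes()
    n1 = config.n_genes // 2
    n2 = (3 * config.n_genes) // 10
    out = []
    for i in range(config.n_genes):
        if i < n1:
            chrom, local = "chr1", i
        elif i < n1 + n2:
            chrom, local = "chr2", i - n1
        else:
            chrom, local = "chr3", i - n1 - n2
        out.append((chrom, local * SLOT + 1000, "+" if i % 2 == 0 else "-"))
    assert all(out[-1][1] + SLOT <= sizes[out[-1][0]] for _ in (0,))
    return out


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts; deterministic rounding at zero dispersion."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return np.rint(mean).astype(np.int64)
    lam = np.where(
        mean > 0,
        rng.gamma(shape=1.0 / dispersion, scale=np.maximum(mean, 1e-300) * dispersion),
        0.0,
    )
    return rng.poisson(lam).astype(np.int64)


def generate_bundle(config: SynthConfig, out_dir: str | Path) -> SynthTruth:
    """Write a complete synthetic input bundle and return its truth ledger."""
    out = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    slots = _slot_coords(config)
    sizes = config.chrom_sizes()

    # --- genes, promoters, element layout -----------------------------------
    genes = []
    for i, (chrom, s0, strand) in enumerate(slots):
        if strand == "+":
            gstart, gend = s0 + 6000, s0 + 6000 + _GENE_LEN
            tss = gstart
        else:
            gstart, gend = s0 + 3000, s0 + 3000 + _GENE_LEN
            tss = gend - 1
        genes.append(
            {"gene_id": f"g{i:04d}", "chrom": chrom, "start": gstart, "end": gend,
             "strand": strand, "tss": tss}
        )
    genes_df = pd.DataFrame(genes)

    elements: list[dict] = []
    for i in range(config.n_distal):
        slot_i, rank = i % config.n_genes, i // config.n_genes
        chrom, s0, strand = slots[slot_i]
        tss = genes[slot_i]["tss"]
        mid = tss - _DISTAL_UPSTREAM[rank] if strand == "+" else tss + _DISTAL_UPSTREAM[rank]
        elements.append(
            {"id": f"enh{i:04d}", "chrom": chrom, "start": mid - _ENH_LEN // 2,
             "end": mid + _ENH_LEN // 2, "strand": ".", "element_class": "enhancer",
             "subclass": "distal", "gene": genes[slot_i]["gene_id"]}
        )
    for i in range(config.n_proximal):
        chrom, s0, strand = slots[i]
        tss = genes[i]["tss"]
        mid = tss - _PROXIMAL_UPSTREAM if strand == "+" else tss + _PROXIMAL_UPSTREAM
        elements.append(
            {"id": f"enh{config.n_distal + i:04d}", "chrom": chrom,
             "start": mid - _ENH_LEN // 2, "end": mid + _ENH_LEN // 2, "strand": ".",
             "element_class": "enhancer", "subclass": "proximal",
             "gene": genes[i]["gene_id"]}
        )
    for i in range(config.n_promoters):
        chrom, s0, strand = slots[i]
        tss = genes[i]["tss"]
        elements.append(
            {"id": f"prom_g{i:04d}", "chrom": chrom, "start": tss - _PROM_HALF,
             "end": tss + _PROM_HALF, "strand": strand, "element_class": "promoter",
             "subclass": "not_applicable", "gene": genes[i]["gene_id"]}
        )
    el_df = pd.DataFrame(elements)

    # decoy enhancers: violate the curation rules, must be removed
    decoys: list[dict] = []
    blacklist_rows: list[dict] = []
    n_black = config.n_decoy - config.n_decoy // 2
    for i in range(config.n_decoy):
        slot_i = i % config.n_genes
        chrom, s0, strand = slots[slot_i]
        if i < config.n_decoy // 2:  # inside a gene body
            g = genes[slot_i]
            start = g["start"] + 100
            reason = "coding_overlap"
        else:  # over a blacklist region placed in the slot's empty zone
            start = s0 + 10_500 if strand == "+" else s0 + 200
            blacklist_rows.append({"chrom": chrom, "start": start - 50, "end": start + 350})
            reason = "blacklist"
        decoys.append(
            {"id": f"decoy{i:03d}", "chrom": chrom, "start": start, "end": start + 300,
             "strand": ".", "element_class": "enhancer", "subclass": "not_applicable",
             "gene": "", "removal_reason": reason}
        )
    blacklist_df = pd.DataFrame(blacklist_rows, columns=["chrom", "start", "end"])

    # --- planted pairs -------------------------------------------------------
    n_pairs = config.n_coordinated_pairs + config.n_distractor_pairs
    if config.n_proximal + n_pairs > min(config.n_distal, config.n_genes, config.n_promoters):
        raise ValueError("not enough pair-free gene slots for planted pairs")
    pair_rows = []
    pair_profile: dict[str, tuple] = {}
    gene_profile_kind: dict[str, str] = {}
    for p in range(n_pairs):
        # each pair claims the first distal enhancer of a slot beyond the
        # proximal-enhancer slots (a proximal enhancer's monotone-down profile
        # would otherwise coincidentally coordinate with a planted down gene
        # in the same regulatory domain) and targets that slot's gene
        s = config.n_proximal + p
        eid = f"enh{s:04d}"
        gid = f"g{s:04d}"
        if p < config.n_coordinated_pairs:
            direction = "down" if p % 2 == 0 else "up"
            planted = "coordinated"
            pair_profile[eid] = (
                config.pair_profile_down if direction == "down" else config.pair_profile_up
            )
            gene_profile_kind[gid] = direction
        else:
            planted = "distractor"
            if p % 2 == 0:  # enhancer down, gene up: direction conflict
                direction = ""
                pair_profile[eid] = config.pair_profile_down
                gene_profile_kind[gid] = "up"
            else:  # enhancer down, gene non-monotone
                direction = ""
                pair_profile[eid] = config.pair_profile_down
                gene_profile_kind[gid] = "bump"
        pair_rows.append(
            {"enhancer_id": eid, "gene_id": gid, "planted": planted, "direction": direction}
        )
    pairs_df = pd.DataFrame(pair_rows)

    # --- RNA fragment counts per element ------------------------------------
    n_el = len(el_df)
    silent = rng.random(n_el) < config.frac_silent
    # planted pair enhancers are never silent: their trajectory is the signal
    silent[np.isin(el_df["id"].to_numpy(), list(pair_profile))] = False

    rna_counts = np.zeros((n_el, 3), dtype=np.int64)
    for t in range(3):
        mean = np.empty(n_el)
        for i, row in enumerate(el_df.itertuples()):
            prof = pair_profile.get(row.id)
            if prof is not None:
                mean[i] = config.pair_baseline_rate * prof[t]
            else:
                cls = row.subclass if row.element_class == "enhancer" else "promoter"
                mean[i] = config.baseline_rate * config.class_profiles[(cls, "RNA")][t]
        mean[silent] = 0.0
        rna_counts[:, t] = _nb_counts(rng, mean, config.dispersion)

    # --- planted ATAC / H3K27ac states and fragment counts -------------------
    state_draw = rng.random((n_el, 2))
    chip_counts = {}
    states = {}
    for a_idx, assay in enumerate(("ATAC", "H3K27ac")):
        st = np.zeros((n_el, 3), dtype=bool)
        for i in range(n_el):
            u = state_draw[i, a_idx]
            if u < config.p_consistent_positive:
                st[i] = True
            elif u < config.p_consistent_positive + config.p_consistent_negative:
                st[i] = False
            else:  # dynamic: a random triple that is neither all-true nor all-false
                pattern = int(rng.integers(1, 7))  # 1..6: the six mixed triples
                st[i] = [(pattern >> b) & 1 for b in range(3)]
        states[assay] = st
        counts = np.zeros((n_el, 3), dtype=np.int64)
        for t in range(3):
            mean = np.empty(n_el)
            for i, row in enumerate(el_df.itertuples()):
                cls = row.subclass if row.element_class == "enhancer" else "promoter"
                base = config.baseline_rate * config.class_profiles[(cls, assay)][t]
                mean[i] = base if st[i, t] else base * config.background_rate
            counts[:, t] = _nb_counts(rng, mean, config.dispersion)
        chip_counts[assay] = counts

    # --- write catalog-side files --------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    (out / "fragments").mkdir(exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    genes_df[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    enh_all = pd.concat(
        [el_df[el_df.element_class == "enhancer"], pd.DataFrame(decoys)], ignore_index=True
    )
    _write_bed6(enh_all, out / "enhancers.bed")
    prom_df = el_df[el_df.element_class == "promoter"]
    _write_bed6(prom_df, out / "promoters.bed")
    prom_df[["id", "gene"]].rename(columns={"id": "promoter_id", "gene": "gene_id"}).to_csv(
        out / "promoter_gene.tsv", sep="\t", index=False
    )
    blacklist_df.to_csv(out / "blacklist.bed", sep="\t", index=False, header=False)
    pd.DataFrame(sorted(sizes.items()), columns=["chrom", "size"]).to_csv(
        out / "chrom_sizes.tsv", sep="\t", index=False, header=False
    )

    # --- fragment files + manifest -------------------------------------------
    manifest_rows = []
    all_counts = {"RNA": rna_counts, "ATAC": chip_counts["ATAC"], "H3K27ac": chip_counts["H3K27ac"]}
    el_start = el_df["start"].to_numpy()
    el_end = el_df["end"].to_numpy()
    el_chrom = el_df["chrom"].to_numpy()
    for assay, counts in all_counts.items():
        for t, tp in enumerate(TIMEPOINTS):
            c = counts[:, t]
            total = int(c.sum())
            starts = np.empty(total, dtype=np.int64)
            chroms = np.empty(total, dtype=object)
            pos = 0
            for i in range(n_el):
                k = int(c[i])
                if k == 0:
                    continue
                lo = el_start[i] - 80
                hi = el_end[i] - 20  # every start in [lo, hi) overlaps the element
                starts[pos : pos + k] = rng.integers(lo, hi, size=k)
                chroms[pos : pos + k] = el_chrom[i]
                pos += k
            frag = pd.DataFrame(
                {"chrom": chroms, "start": starts, "end": starts + config.fragment_length}
            )
            rel = f"fragments/{assay}_{tp}.bed"
            frag.to_csv(out / rel, sep="\t", index=False, header=False)
            manifest_rows.append(
                {"sample": f"{assay}_{tp}", "assay": assay, "timepoint": tp,
                 "path": rel, "total_count": max(config.library_size, total, 1)}
            )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)

    # --- peaks from planted states (boundary jitter only) ---------------------
    # background ATAC peaks sit in the per-slot zone that no element, gene pad
    # or blacklist region can reach, so they are eligible "random accessible"
    # pool members at every timepoint
    bg_slots = rng.choice(len(slots), size=min(config.n_background_peaks, len(slots)),
                          replace=False)
    background = []
    for si in sorted(bg_slots):
        chrom, s0, strand = slots[si]
        start = s0 + 11_200 if strand == "+" else s0 + 600
        background.append({"chrom": chrom, "start": start, "end": start + 500})
    for assay in ("ATAC", "H3K27ac"):
        st = states[assay]
        for t, tp in enumerate(TIMEPOINTS):
            rows = [] if assay != "ATAC" else list(background)
            for i in range(n_el):
                if not st[i, t]:
                    continue
                length = int(el_end[i] - el_start[i])
                j = int(round(config.peak_jitter * length))
                ds = int(rng.integers(-j, j + 1)) if j else 0
                de = int(rng.integers(-j, j + 1)) if j else 0
                rows.append(
                    {"chrom": el_chrom[i], "start": max(0, el_start[i] + ds),
                     "end": el_end[i] + de}
                )
            pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
                out / f"peaks/{assay}_{tp}.bed", sep="\t", index=False, header=False
            )

    # --- p53 peaks -------------------------------------------------------------
    n_bound = int(round(config.p53_bound_frac * n_el))
    bound_idx = np.sort(rng.choice(n_el, size=n_bound, replace=False))
    p53_rows = [
        {"chrom": el_chrom[i], "start": max(0, el_start[i] - 50), "end": el_end[i] + 50}
        for i in bound_idx
    ]
    pd.DataFrame(p53_rows, columns=["chrom", "start", "end"]).to_csv(
        out / "peaks/p53.bed", sep="\t", index=False, header=False
    )
    p53_bound = set(el_df["id"].to_numpy()[bound_idx])

    # --- footprints -------------------------------------------------------------
    tf_names = [f"TF{i:03d}" for i in range(config.n_tf)]
    for i in range(0, config.n_tf, 10):  # sprinkle complex names
        tf_names[i] = f"TF{i:03d}::TF{i:03d}B"
    hi_var = tf_names[: config.n_hi_var_tf]
    fp_rows = []
    enh_idx = np.flatnonzero((el_df.element_class == "enhancer").to_numpy())
    prom_idx = np.flatnonzero((el_df.element_class == "promoter").to_numpy())
    for tf_i, tf in enumerate(tf_names):
        base = 4.0 + 2.0 * rng.random()
        if tf in hi_var:
            mult = (0.4, 2.0, 0.1) if tf_i % 2 == 0 else (0.1, 0.8, 2.0)
        else:
            mult = tuple(1.0 + 0.02 * rng.standard_normal() for _ in range(3))
        for cls_idx in (enh_idx, prom_idx):
            for t, tp in enumerate(TIMEPOINTS):
                homes = rng.choice(cls_idx, size=config.footprints_per_tf, replace=False)
                for h in homes:
                    start = int(el_start[h] + rng.integers(0, el_end[h] - el_start[h] - 20))
                    prot = base * mult[t] + 0.05 * rng.standard_normal()
                    fp_rows.append(
                        {"tf_name": tf, "chrom": el_chrom[h], "start": start,
                         "end": start + 20,
                         "protection_score": round(float(prot), 4),
                         "tag_count": int(max(0, round(prot * 10 + rng.standard_normal()))),
                         "timepoint": tp}
                    )
    pd.DataFrame(fp_rows).to_csv(out / "footprints.tsv", sep="\t", index=False)

    # --- loops over planted + distractor pairs ---------------------------------
    loop_rows = []
    el_by_id = el_df.set_index("id")
    for r in pairs_df.itertuples():
        e = el_by_id.loc[r.enhancer_id]
        p = el_by_id.loc[f"prom_{r.gene_id}"]
        loop_rows.append(
            {"chrom1": e.chrom, "start1": int(e.start) - 100, "end1": int(e.end) + 100,
             "chrom2": p.chrom, "start2": int(p.start) - 100, "end2": int(p.end) + 100}
        )
    pd.DataFrame(loop_rows).to_csv(out / "loops.tsv", sep="\t", index=False, header=False)

    # --- gene expression (TPM) and DE tables ------------------------------------
    gene_ids = genes_df["gene_id"].tolist()
    n_extra_up = config.n_de_extra - config.n_de_extra // 2
    spare = [g for g in gene_ids if g not in gene_profile_kind]
    extra_up = spare[:n_extra_up]
    extra_down = spare[n_extra_up : config.n_de_extra]
    expr_rows, de8_rows, de16_rows = [], [], []
    for gid in gene_ids:
        kind = gene_profile_kind.get(gid, "flat")
        base = 20.0 + 60.0 * rng.random()
        prof = {
            "down": (1.0, 0.5, 0.25),
            "up": (0.25, 0.5, 1.0),
            "bump": (1.0, 1.6, 0.8),
            "flat": (1.0, 1.0, 1.0),
        }[kind]
        noise = np.exp(config.gene_noise_sigma * rng.standard_normal(3))
        tpm = base * np.asarray(prof) * noise
        expr_rows.append(
            {"gene_id": gid, "tpm_0h": round(tpm[0], 4), "tpm_8h": round(tpm[1], 4),
             "tpm_16h": round(tpm[2], 4)}
        )
        # DE tables: planted monotone genes and the extra DE genes pass both
        # contrasts; everything else is null
        if kind in ("down", "up") or gid in extra_up or gid in extra_down:
            sign = 1.0 if (kind == "up" or gid in extra_up) else -1.0
            lfc8 = sign * float(1.5 + rng.random())
            lfc16 = sign * float(2.0 + rng.random())
            fdr8 = float(10 ** (-6 + 3 * rng.random()))
            fdr16 = float(10 ** (-6 + 3 * rng.random()))
        else:
            lfc8 = float(0.3 * rng.standard_normal())
            lfc16 = float(0.3 * rng.standard_normal())
            fdr8 = float(0.1 + 0.9 * rng.random())
            fdr16 = float(0.1 + 0.9 * rng.random())
        de8_rows.append({"gene_id": gid, "log2fc": round(lfc8, 4), "fdr": fdr8})
        de16_rows.append({"gene_id": gid, "log2fc": round(lfc16, 4), "fdr": fdr16})
    pd.DataFrame(expr_rows).to_csv(out / "gene_expression.tsv", sep="\t", index=False)
    pd.DataFrame(de8_rows).to_csv(out / "de_8h_vs_0h.tsv", sep="\t", index=False)
    pd.DataFrame(de16_rows).to_csv(out / "de_16h_vs_0h.tsv", sep="\t", index=False)
    pd.Series(sorted(extra_up)).to_csv(out / "truth/de_extra_up.txt", index=False, header=False)
    pd.Series(sorted(extra_down)).to_csv(out / "truth/de_extra_down.txt", index=False, header=False)

    # --- truth ledger -------------------------------------------------------------
    truth_el = el_df[["id", "element_class", "subclass"]].copy()
    for assay in ("ATAC", "H3K27ac"):
        for t, tp in enumerate(TIMEPOINTS):
            truth_el[f"{assay.lower()}_{tp}"] = states[assay][:, t]
    for t, tp in enumerate(TIMEPOINTS):
        truth_el[f"rna_count_{tp}"] = rna_counts[:, t]
    truth_el["p53_bound"] = truth_el["id"].isin(p53_bound)
    decoy_truth = pd.DataFrame(
        [{"id": d["id"], "element_class": "enhancer", "subclass": "not_applicable",
          "removal_reason": d["removal_reason"]} for d in decoys]
    )
    truth_el["removal_reason"] = ""
    truth_all = pd.concat([truth_el, decoy_truth], ignore_index=True).fillna(
        {"removal_reason": ""}
    )
    truth_all.to_csv(out / "truth/elements.tsv", sep="\t", index=False)
    pairs_df.to_csv(out / "truth/pairs.tsv", sep="\t", index=False)
    pd.Series(hi_var).to_csv(out / "truth/hi_var_tfs.txt", index=False, header=False)

    with open(out / "config.yaml", "w") as fh:
        cfg = {k: v for k, v in vars(config).items() if k != "class_profiles"}
        cfg["class_profiles"] = {
            f"{cls}/{assay}": list(prof) for (cls, assay), prof in config.class_profiles.items()
        }
        yaml.safe_dump(cfg, fh, sort_keys=True)

    return SynthTruth(truth_all, pairs_df, list(hi_var), p53_bound)


def _write_bed6(df: pd.DataFrame, path: Path) -> None:
    bed = df[["chrom", "start", "end", "id"]].copy()
    bed["score"] = 0
    bed["strand"] = df["strand"].to_numpy()
    bed.to_csv(path, sep="\t", index=False, header=False)


def load_truth(bundle_dir: str | Path) -> SynthTruth:
    d = Path(bundle_dir)
    elements = pd.read_csv(d / "truth/elements.tsv", sep="\t").fillna({"removal_reason": ""})
    pairs = pd.read_csv(d / "truth/pairs.tsv", sep="\t").fillna({"direction": ""})
    hi_var = pd.read_csv(d / "truth/hi_var_tfs.txt", header=None)[0].tolist()
    p53 = set(elements.loc[elements.get("p53_bound") == True, "id"])  # noqa: E712
    return SynthTruth(elements, pairs, hi_var, p53)


# ---------------------------------------------------------------------------
# recovery metrics


def _precision_recall(found: set, truth: set) -> tuple[float, float]:
    if not found:
        return (1.0 if not truth else 0.0, 0.0 if truth else 1.0)
    tp = len(found & truth)
    return tp / len(found), (tp / len(truth) if truth else 1.0)


def truth_report(truth: SynthTruth, outputs: Mapping[str, object]) -> pd.DataFrame:
    """Per-stage precision/recall of pipeline outputs against the planted truth.

    ``outputs`` may provide: ``trajectories`` (DataFrame with element_id,
    assay, category), ``pairs`` (DataFrame with enhancer_id, gene_id,
    direction), ``top_tfs`` (sequence of TF names), ``p53`` (an object with
    p53BER/p53BPR sets or a set of bound ids).
    """
    rows = []
    kept = truth.elements[truth.elements["removal_reason"] == ""]

    traj = outputs.get("trajectories")
    if traj is not None:
        known = set(kept["id"])
        bad = set(traj["element_id"]) - known
        if bad:
            raise ValueError(f"trajectory ids not in truth: {sorted(bad)[:5]}")
        for assay in sorted(set(traj["assay"])):
            sub = traj[traj.assay == assay].set_index("element_id")["category"]
            col = assay.lower()
            if f"{col}_0h" in kept.columns:
                states = kept[[f"{col}_{tp}" for tp in TIMEPOINTS]].to_numpy(dtype=bool)
            elif assay == "RNA":
                states = kept[[f"rna_count_{tp}" for tp in TIMEPOINTS]].to_numpy() > 0
            else:
                continue
            expected = np.where(
                states.all(axis=1),
                "consistent_positive",
                np.where(~states.any(axis=1), "consistent_negative", "dynamic"),
            )
            expected_s = pd.Series(expected, index=kept["id"])
            common = sub.index.intersection(expected_s.index)
            acc = float((sub.loc[common] == expected_s.loc[common]).mean())
            rows.append({"stage": f"trajectory_{assay}", "metric": "accuracy", "value": acc})

    found_pairs = outputs.get("pairs")
    if found_pairs is not None:
        truth_set = {
            (r.enhancer_id, r.gene_id, r.direction)
            for r in truth.pairs.itertuples()
            if r.planted == "coordinated"
        }
        found_set = {
            (r.enhancer_id, r.gene_id, r.direction) for r in found_pairs.itertuples()
        }
        prec, rec = _precision_recall(found_set, truth_set)
        rows.append({"stage": "coordinated_pairs", "metric": "precision", "value": prec})
        rows.append({"stage": "coordinated_pairs", "metric": "recall", "value": rec})

    top_tfs = outputs.get("top_tfs")
    if top_tfs is not None:
        planted = set(truth.hi_var_tfs)
        rec = len(set(top_tfs) & planted) / len(planted) if planted else 1.0
        rows.append({"stage": "top_tfs", "metric": "recall", "value": rec})

    p53 = outputs.get("p53")
    if p53 is not None:
        if hasattr(p53, "p53BER"):
            found = set(p53.p53BER) | set(p53.p53BPR)
        else:
            found = set(p53)
        prec, rec = _precision_recall(found, truth.p53_bound)
        rows.append({"stage": "p53_partition", "metric": "precision", "value": prec})
        rows.append({"stage": "p53_partition", "metric": "recall", "value": rec})

    return pd.DataFrame(rows, columns=["stage", "metric", "value"])
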