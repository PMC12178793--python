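"""Stage orchestration: simulate -> curate -> quantify -> states -> pairs ->
tfdyn -> compare -> report, driven by a YAML run configuration.

Each stage reads the artifacts of its prerequisites from the output
directory, writes its own TSV outputs under ``<out>/<stage>/`` together with
a ``manifest.json`` parameter snapshot, and never mutates its inputs, so a
rerun with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import build_catalog, read_bed, read_catalog, read_genes, write_catalog
from .pairs import (
    assign_by_domain,
    assign_by_loops,
    build_domains,
    consistent_de_genes,
    coordinated_pairs,
    read_de_table,
    read_loops,
)
from .signal import read_fragment_manifest, region_rpm_batch
from .states import PeakSet, random_accessible_regions, random_regions, trajectory_table
from .stats import friedman, ks2
from .synthdata import SynthConfig, generate_bundle, load_truth, truth_report
from .tfdyn import (
    build_activity_table,
    footprints_in_elements,
    partition_by_p53,
    rank_by_sd,
    read_footprints,
    top_overlap,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "curate", "quantify", "states", "pairs", "tfdyn", "compare", "report")
TIMEPOINTS = ("0h", "8h", "16h")

__all__ = ["RunConfig", "run_stage", "run_all", "STAGES"]


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    out_dir: Path
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None,
                  seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        out = Path(out_dir) if out_dir is not None else Path(raw.get("out_dir", "credyn_out"))
        cfg = cls(
            out_dir=out,
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            inputs=dict(raw.get("inputs", {})),
            params={k: dict(v) for k, v in raw.items()
                    if isinstance(v, dict) and k not in ("inputs",)},
        )
        return cfg

    def stage_params(self, stage: str) -> dict[str, Any]:
        return dict(self.params.get(stage, {}))

    def input_path(self, key: str, default_rel: str | None = None) -> Path:
        """Resolve an input: explicit config path, else the simulate bundle."""
        if key in self.inputs:
            return Path(self.inputs[key])
        if default_rel is not None:
            cand = self.out_dir / "simulate" / default_rel
            if cand.exists():
                return cand
        raise FileNotFoundError(
            f"input '{key}' not configured and not found in the simulate stage output; "
            "run the 'simulate' stage first or set inputs."
        )


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing prerequisite artifact {path}; run the '{stage}' stage first"
        )
    return path


def _write_manifest(stage_dir: Path, config: RunConfig, params: Mapping[str, Any],
                    tables: Mapping[str, int], inputs: Mapping[str, str]) -> None:
    def _rel(p: str) -> str:
        # paths inside the run directory are recorded relative to it so that
        # two runs of the same config produce byte-identical manifests
        try:
            return str(Path(p).resolve().relative_to(config.out_dir.resolve()))
        except (ValueError, OSError):
            return str(p)

    manifest = {
        "stage": stage_dir.name,
        "version": __version__,
        "seed": config.seed,
        "params": dict(params),
        "inputs": {k: _rel(v) for k, v in inputs.items()},
        "row_counts": dict(tables),
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig) -> None:
    params = config.stage_params("simulate")
    params.setdefault("seed", config.seed)
    profiles = params.pop("class_profiles", None)
    synth = SynthConfig(**params)
    if profiles:
        synth.class_profiles.update(
            {tuple(k.split("/")): tuple(v) for k, v in profiles.items()}
        )
    out = config.out_dir / "simulate"
    generate_bundle(synth, out)
    _write_manifest(out, config, vars(synth) | {"class_profiles": "see config.yaml"},
                    {}, {})


def _stage_curate(config: RunConfig) -> None:
    params = config.stage_params("curate")
    pad = int(params.get("pad", 1000))
    enh_path = config.input_path("enhancers", "enhancers.bed")
    prom_path = config.input_path("promoters", "promoters.bed")
    gene_path = config.input_path("genes", "genes.tsv")
    try:
        black_path = config.input_path("blacklist", "blacklist.bed")
        blacklist = read_bed(black_path)
    except FileNotFoundError:
        black_path, blacklist = None, []
    enhancers = read_bed(enh_path)
    promoters = read_bed(prom_path)
    genes = read_genes(gene_path)
    catalog, removals = build_catalog(
        enhancers, promoters, genes, blacklist, pad=pad,
        provenance=f"curated from {enh_path}",
    )
    out = config.out_dir / "curate"
    out.mkdir(parents=True, exist_ok=True)
    write_catalog(catalog, out / "catalog.tsv")
    removals.to_csv(out / "removed.tsv", sep="\t", index=False)
    _write_manifest(out, config, {"pad": pad},
                    {"catalog": len(catalog), "removed": len(removals)},
                    {"enhancers": str(enh_path), "promoters": str(prom_path),
                     "genes": str(gene_path), "blacklist": str(black_path)})


def _stage_quantify(config: RunConfig) -> None:
    catalog = read_catalog(_require(config.out_dir / "curate/catalog.tsv", "curate"))
    manifest_path = config.input_path("manifest", "manifest.tsv")
    sets = read_fragment_manifest(manifest_path)
    out = config.out_dir / "quantify"
    out.mkdir(parents=True, exist_ok=True)
    regions = [e.interval for e in catalog]
    ids = [e.id for e in catalog]
    tables = {}
    for assay in sorted({s.assay for s in sets}):
        cols = {"element_id": ids}
        for tp in TIMEPOINTS:
            fs = [s for s in sets if s.assay == assay and s.timepoint == tp]
            if not fs:
                raise FileNotFoundError(f"manifest lacks {assay} fragments at {tp}")
            cols[f"rpm_{tp}"] = np.round(region_rpm_batch(fs[0], regions), 6)
        df = pd.DataFrame(cols)
        if assay == "RNA":
            df["expressed_0h"] = df["rpm_0h"] > 0
        df.to_csv(out / f"rpm_{assay}.tsv", sep="\t", index=False)
        tables[f"rpm_{assay}"] = len(df)
    _write_manifest(out, config, {}, tables, {"manifest": str(manifest_path)})


def _read_peaksets(config: RunConfig, assay: str) -> list[PeakSet]:
    sets = []
    for tp in TIMEPOINTS:
        key = f"peaks_{assay}_{tp}"
        path = config.input_path(key, f"peaks/{assay}_{tp}.bed")
        sets.append(PeakSet(assay, tp, read_bed(path)))
    return sets


def _stage_states(config: RunConfig) -> None:
    params = config.stage_params("states")
    catalog = read_catalog(_require(config.out_dir / "curate/catalog.tsv", "curate"))
    out = config.out_dir / "states"
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for assay in ("ATAC", "H3K27ac"):
        peaksets = _read_peaksets(config, assay)
        frames.append(trajectory_table(list(catalog), peaksets, assay))
    # RNA trajectories from the quantify stage RPM table
    rpm_path = _require(config.out_dir / "quantify/rpm_RNA.tsv", "quantify")
    rpm = pd.read_csv(rpm_path, sep="\t")
    states_bool = rpm[[f"rpm_{tp}" for tp in TIMEPOINTS]].to_numpy() > 0
    rna = pd.DataFrame(
        {
            "element_id": rpm["element_id"],
            "assay": "RNA",
            **{f"state_{tp}": states_bool[:, i] for i, tp in enumerate(TIMEPOINTS)},
            "category": np.where(
                states_bool.all(axis=1), "consistent_positive",
                np.where(~states_bool.any(axis=1), "consistent_negative", "dynamic"),
            ),
        }
    )
    frames.append(rna)
    traj = pd.concat(frames, ignore_index=True)
    traj.to_csv(out / "trajectories.tsv", sep="\t", index=False)

    sizes = pd.read_csv(
        config.input_path("chrom_sizes", "chrom_sizes.tsv"), sep="\t", header=None
    )
    chrom_sizes = dict(zip(sizes[0], sizes[1].astype(int)))
    rand = random_regions(
        chrom_sizes,
        n=int(params.get("n_random_regions", 10_000)),
        length=int(params.get("random_length", 2000)),
        seed=config.seed,
    )
    pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end, "id": r.id} for r in rand]
    ).to_csv(out / "random_regions.bed", sep="\t", index=False, header=False)
    atac0 = _read_peaksets(config, "ATAC")[0]
    rar, truncated = random_accessible_regions(
        atac0, catalog, n=int(params.get("n_random_accessible", 200)), seed=config.seed
    )
    pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end} for r in rar]
    ).to_csv(out / "random_accessible.bed", sep="\t", index=False, header=False)
    if truncated:
        logger.warning("fewer eligible accessible regions than requested")
    _write_manifest(out, config, params,
                    {"trajectories": len(traj), "random_regions": len(rand),
                     "random_accessible": len(rar)}, {})


def _stage_pairs(config: RunConfig) -> None:
    params = config.stage_params("pairs")
    catalog = read_catalog(_require(config.out_dir / "curate/catalog.tsv", "curate"))
    genes = read_genes(config.input_path("genes", "genes.tsv"))
    loops = read_loops(config.input_path("loops", "loops.tsv"))
    prom_gene = pd.read_csv(config.input_path("promoter_gene", "promoter_gene.tsv"), sep="\t")
    promoter_gene = dict(zip(prom_gene["promoter_id"], prom_gene["gene_id"]))
    de8 = read_de_table(config.input_path("de_8h", "de_8h_vs_0h.tsv"), "8h_vs_0h")
    de16 = read_de_table(config.input_path("de_16h", "de_16h_vs_0h.tsv"), "16h_vs_0h")
    expr = pd.read_csv(config.input_path("gene_expression", "gene_expression.tsv"), sep="\t")
    rpm = pd.read_csv(_require(config.out_dir / "quantify/rpm_RNA.tsv", "quantify"), sep="\t")

    sizes = pd.read_csv(
        config.input_path("chrom_sizes", "chrom_sizes.tsv"), sep="\t", header=None
    )
    chrom_sizes = dict(zip(sizes[0], sizes[1].astype(int)))
    domains = build_domains(
        genes,
        basal_up=int(params.get("basal_up", 5000)),
        basal_down=int(params.get("basal_down", 1000)),
        max_ext=int(params.get("max_ext", 1_000_000)),
        chrom_sizes=chrom_sizes,
    )
    enhancers = catalog.enhancers
    loop_pairs = assign_by_loops(enhancers, catalog.promoters, promoter_gene, loops)
    loop_set = {(p.enhancer_id, p.gene_id) for p in loop_pairs}
    domain_rows = []
    for e in enhancers:
        for g in assign_by_domain(e, domains):
            domain_rows.append((e.id, g))
    domain_set = set(domain_rows)
    from .pairs import PairRecord

    all_pairs = [
        PairRecord(e, g, "both" if (e, g) in loop_set and (e, g) in domain_set
                   else ("loop" if (e, g) in loop_set else "domain"))
        for e, g in sorted(loop_set | domain_set)
    ]
    enh_rpm = {
        r.element_id: tuple(getattr(r, f"rpm_{tp}") for tp in TIMEPOINTS)
        for r in rpm.itertuples()
    }
    gene_expr = {
        r.gene_id: tuple(getattr(r, f"tpm_{tp}") for tp in TIMEPOINTS)
        for r in expr.itertuples()
    }
    coord = coordinated_pairs(all_pairs, enh_rpm, gene_expr,
                              eps=float(params.get("eps", 0.0)))
    up, down = consistent_de_genes(
        de8, de16,
        lfc_min=float(params.get("lfc_min", 1.0)),
        fdr_max=float(params.get("fdr_max", 0.05)),
    )
    out = config.out_dir / "pairs"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"enhancer_id": p.enhancer_id, "gene_id": p.gene_id, "evidence": p.evidence}
         for p in all_pairs]
    ).to_csv(out / "candidate_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"enhancer_id": p.enhancer_id, "gene_id": p.gene_id, "evidence": p.evidence,
          "direction": p.direction} for p in coord]
    ).to_csv(out / "coordinated_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted([(g, "up") for g in up] + [(g, "down") for g in down]),
        columns=["gene_id", "direction"],
    ).to_csv(out / "consistent_de_genes.tsv", sep="\t", index=False)
    _write_manifest(out, config, params,
                    {"candidate_pairs": len(all_pairs), "coordinated_pairs": len(coord),
                     "consistent_de_genes": len(up) + len(down)}, {})


def _stage_tfdyn(config: RunConfig) -> None:
    params = config.stage_params("tfdyn")
    catalog = read_catalog(_require(config.out_dir / "curate/catalog.tsv", "curate"))
    footprints = read_footprints(config.input_path("footprints", "footprints.tsv"))
    p53 = PeakSet("p53", "static", read_bed(config.input_path("p53_peaks", "peaks/p53.bed")))
    metric = params.get("metric", "combined")
    top_n = int(params.get("top_n", 30))
    out = config.out_dir / "tfdyn"
    out.mkdir(parents=True, exist_ok=True)

    from .catalog import ElementCatalog

    tops = {}
    for cls in ("enhancer", "promoter"):
        sub = ElementCatalog(catalog.subset(cls))
        fps, counts = footprints_in_elements(footprints, sub)
        table = build_activity_table(fps, metric=metric)
        ranked = rank_by_sd(table, top_n=top_n)
        tops[cls] = ranked
        rows = [
            {"tf_name": tf, "activity_0h": table.rows[tf][0],
             "activity_8h": table.rows[tf][1], "activity_16h": table.rows[tf][2],
             "sd": float(np.std(table.rows[tf], ddof=1))}
            for tf in ranked
        ]
        pd.DataFrame(rows).to_csv(out / f"top_tfs_{cls}.tsv", sep="\t", index=False)
    shared, n_shared = top_overlap(tops["enhancer"], tops["promoter"])
    pd.Series(sorted(shared)).to_csv(out / "shared_top_tfs.txt", index=False, header=False)

    part = partition_by_p53(catalog, p53)
    rows = []
    for name, ids in (("p53BER", part.p53BER), ("p53FER", part.p53FER),
                      ("p53BPR", part.p53BPR), ("p53FPR", part.p53FPR)):
        rows.extend({"element_id": i, "partition": name} for i in sorted(ids))
    pd.DataFrame(rows).to_csv(out / "p53_partition.tsv", sep="\t", index=False)
    _write_manifest(out, config, {"metric": metric, "top_n": top_n},
                    {"shared_top_tfs": n_shared, "p53_partition": len(rows)}, {})


def _stage_compare(config: RunConfig) -> None:
    """The nonparametric test battery over quantified signal."""
    catalog = read_catalog(_require(config.out_dir / "curate/catalog.tsv", "curate"))
    out = config.out_dir / "compare"
    out.mkdir(parents=True, exist_ok=True)
    class_of = {
        e.id: (e.subclass if e.element_class == "enhancer" else "promoter")
        for e in catalog
    }
    rows = []
    rpm_tables = {}
    for assay in ("RNA", "ATAC", "H3K27ac"):
        path = _require(config.out_dir / f"quantify/rpm_{assay}.tsv", "quantify")
        rpm = pd.read_csv(path, sep="\t")
        rpm["cls"] = rpm["element_id"].map(class_of)
        rpm_tables[assay] = rpm
        for cls, grp in rpm.groupby("cls"):
            mat = grp[[f"rpm_{tp}" for tp in TIMEPOINTS]].to_numpy()
            if len(mat) < 2:
                continue
            res = friedman(mat)
            means = mat.mean(axis=0)
            rows.append(
                {"assay": assay, "group": cls, "test": res.method, "n": len(mat),
                 "statistic": round(res.statistic, 6), "p_value": res.p_value,
                 "stars": res.stars,
                 "mean_0h": round(means[0], 4), "mean_8h": round(means[1], 4),
                 "mean_16h": round(means[2], 4)}
            )
    friedman_df = pd.DataFrame(rows)
    friedman_df.to_csv(out / "friedman_by_class.tsv", sep="\t", index=False)

    # KS comparisons: p53-bound vs p53-free, per class side, per assay/timepoint
    ks_rows = []
    part_path = config.out_dir / "tfdyn/p53_partition.tsv"
    if part_path.exists():
        part = pd.read_csv(part_path, sep="\t")
        groups = {n: set(part.loc[part.partition == n, "element_id"]) for n in
                  ("p53BER", "p53FER", "p53BPR", "p53FPR")}
        for assay, rpm in rpm_tables.items():
            vals = rpm.set_index("element_id")
            for a, b in (("p53BER", "p53FER"), ("p53BPR", "p53FPR")):
                for tp in TIMEPOINTS:
                    x = vals.loc[vals.index.isin(groups[a]), f"rpm_{tp}"].to_numpy()
                    y = vals.loc[vals.index.isin(groups[b]), f"rpm_{tp}"].to_numpy()
                    if len(x) == 0 or len(y) == 0:
                        continue
                    res = ks2(x, y)
                    ks_rows.append(
                        {"group_a": a, "group_b": b, "assay": assay, "timepoint": tp,
                         "D": round(res.statistic, 6), "p_value": res.p_value,
                         "method": res.method, "stars": res.stars}
                    )
    pd.DataFrame(ks_rows).to_csv(out / "ks_comparisons.tsv", sep="\t", index=False)
    _write_manifest(out, config, {},
                    {"friedman": len(friedman_df), "ks": len(ks_rows)}, {})


def _stage_report(config: RunConfig) -> None:
    bundle = config.out_dir / "simulate"
    if not (bundle / "truth/elements.tsv").exists():
        raise FileNotFoundError(
            "report requires a simulated bundle with truth tables; run 'simulate' first"
        )
    truth = load_truth(bundle)
    outputs: dict[str, object] = {}
    traj_path = _require(config.out_dir / "states/trajectories.tsv", "states")
    outputs["trajectories"] = pd.read_csv(traj_path, sep="\t")
    pairs_path = _require(config.out_dir / "pairs/coordinated_pairs.tsv", "pairs")
    outputs["pairs"] = pd.read_csv(pairs_path, sep="\t")
    top_path = _require(config.out_dir / "tfdyn/top_tfs_enhancer.tsv", "tfdyn")
    outputs["top_tfs"] = pd.read_csv(top_path, sep="\t")["tf_name"].tolist()
    part = pd.read_csv(config.out_dir / "tfdyn/p53_partition.tsv", sep="\t")
    outputs["p53"] = set(part.loc[part.partition.isin(["p53BER", "p53BPR"]), "element_id"])
    report = truth_report(truth, outputs)
    out = config.out_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "recovery.tsv", sep="\t", index=False)
    _write_manifest(out, config, {}, {"recovery": len(report)}, {})


_STAGE_FN = {
    "simulate": _stage_simulate,
    "curate": _stage_curate,
    "quantify": _stage_quantify,
    "states": _stage_states,
    "pairs": _stage_pairs,
    "tfdyn": _stage_tfdyn,
    "compare": _stage_compare,
    "report": _stage_report,
}


def run_stage(stage: str, config: RunConfig) -> None:
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage '{stage}'; choose from {STAGES}")
    logger.info("running stage %s -> %s", stage, config.out_dir / stage)
    _STAGE_FN[stage](config)


def run_all(config: RunConfig, stages: tuple[str, ...] = STAGES) -> None:
    for stage in stages:
        run_stage(stage, config)
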