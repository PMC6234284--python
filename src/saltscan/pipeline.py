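"""End-to-end orchestration: simulate -> cluster -> scan -> unifrac -> shared -> detect.

One JSON config drives the run; every stochastic stage derives its seed from
the config seed, so a rerun with the same config is byte-identical.  The
manifest records parameters and the SHA-256 of every output file, with no
timestamps, to make determinism checkable by file comparison.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from saltscan import __version__
from saltscan.cluster import farthest_neighbor_cluster
from saltscan.detect import (
    DetectionParams,
    detection_probability,
    detection_probability_poisson,
    establishment_appearances,
)
from saltscan.scan import group_scan
from saltscan.seqdist import AlignedSequenceSet, pairwise_distance
from saltscan.sharing import accumulation_curve, filter_groups, find_shared_taxa, fold_enrichment
from saltscan.simulate import SyntheticSpec, simulate_community, write_community
from saltscan.unifrac import (
    independent_swap_null,
    lineage_groups,
    permanova,
    pooled_group_unifrac,
    rarefy,
    sample_pair_unifrac,
    unweighted_unifrac,
    z_test,
)

ALL_STAGES = ("simulate", "cluster", "scan", "unifrac", "shared", "detect")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the study's stated parameters."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulate: dict = dc_field(default_factory=dict)
    inputs: dict = dc_field(default_factory=dict)  # fasta/tree/counts/metadata/lineage paths
    grid_step: float = 0.001
    scan_rank: int = 1  # phylum
    group_rank: int = 1
    rarefaction_depth: int = 9827
    n_nulls: int = 1000
    n_permutations: int = 999
    n_orderings: int = 100
    weighted: bool = False
    min_samples_per_habitat: int = 3
    min_taxa: int = 5
    min_sequences: int = 500
    detect: dict = dc_field(
        default_factory=lambda: {
            "population_density": 1.0,
            "community_density": 500000.0,
            "library_size": 150000,
            "selective_advantages": [0.1, 0.001],
        }
    )

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(self.stages)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["stages"] = list(self.stages)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(
    fasta=None, tree=None, counts=None, metadata=None, lineage=None
) -> list[str]:
    """Cross-check the pipeline inputs; returns a list of violations (empty = clean)."""
    violations: list[str] = []
    seqs = tre = cnt = meta = lin = None
    if fasta is not None:
        try:
            seqs = AlignedSequenceSet.from_fasta(fasta)
        except ValueError as exc:
            violations.append(f"alignment: {exc}")
    if tree is not None:
        try:
            tre = TreeNode.read(str(tree))
        except Exception as exc:  # malformed newick
            violations.append(f"tree: unreadable newick ({exc})")
    if counts is not None:
        cnt = pd.read_csv(counts, sep="\t", index_col=0)
        if (cnt < 0).any().any():
            violations.append("counts: negative entries")
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t")
        for column in ("sample_id", "habitat"):
            if column not in meta.columns:
                violations.append(f"metadata: missing column {column!r}")
                meta = None
                break
        if meta is not None:
            bad = set(meta["habitat"]) - {"marine", "freshwater"}
            if bad:
                violations.append(f"metadata: habitat labels outside vocabulary: {sorted(bad)}")
    if lineage is not None:
        lin = pd.read_csv(lineage, sep="\t", index_col=0).iloc[:, 0]
    if tre is not None and cnt is not None:
        tips = {t.name for t in tre.tips()}
        missing = tips - set(cnt.index)
        if missing:
            violations.append(f"tree: {len(missing)} tip(s) absent from count table, e.g. {sorted(missing)[:3]}")
        extra = set(cnt.index) - tips
        if extra:
            violations.append(f"counts: {len(extra)} taxa absent from tree, e.g. {sorted(extra)[:3]}")
    if seqs is not None and cnt is not None:
        if set(seqs.ids) != set(cnt.index):
            violations.append("alignment ids and count-table taxa disagree")
    if meta is not None and cnt is not None:
        missing = set(cnt.columns) - set(meta["sample_id"])
        if missing:
            violations.append(f"metadata: missing sample(s) {sorted(missing)}")
    if lin is not None and cnt is not None:
        missing = set(cnt.index) - set(lin.index)
        if missing:
            violations.append(f"lineage: {len(missing)} taxa uncovered")
    return violations


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_check"
    probe.write_text("ok")
    probe.unlink()

    manifest: dict = {
        "saltscan_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def record(stage: str, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in files.items()
        }

    paths = dict(config.inputs)
    if "simulate" in config.stages:
        spec_kwargs = dict(config.simulate)
        spec_kwargs.setdefault("seed", config.seed)
        spec_kwargs.setdefault("n_taxa", 60)
        spec = SyntheticSpec(**spec_kwargs)
        com = simulate_community(spec)
        written = write_community(com, out / "simulate")
        record("simulate", {k: Path(v) for k, v in written.items()})
        paths = {
            "fasta": written["fasta"],
            "tree": written["tree"],
            "counts": written["counts"],
            "metadata": written["metadata"],
            "lineage": written["lineage"],
        }

    needs_inputs = set(config.stages) - {"simulate", "detect"}
    seqs = tree = counts = metadata = lineage = None
    if needs_inputs:
        required = ["fasta", "tree", "counts", "metadata", "lineage"]
        missing = [k for k in required if k not in paths]
        if missing:
            raise FileNotFoundError(
                f"stages {sorted(needs_inputs)} need inputs {missing}: "
                "enable the simulate stage or provide paths in config.inputs"
            )
        violations = validate_inputs(**{k: paths[k] for k in required})
        if violations:
            raise ValueError("input validation failed: " + "; ".join(violations))
        counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
        metadata = pd.read_csv(paths["metadata"], sep="\t")
        lineage = pd.read_csv(paths["lineage"], sep="\t", index_col=0).iloc[:, 0]
        seqs = AlignedSequenceSet.from_fasta(paths["fasta"], counts=counts, lineage=lineage)
        tree = TreeNode.read(paths["tree"])

    clusterings = {}
    if "cluster" in config.stages:
        stage_dir = out / "cluster"
        stage_dir.mkdir(exist_ok=True)
        groups = lineage_groups(lineage, config.scan_rank)
        rows = []
        list_lines = []
        for group in sorted(groups):
            members = [t for t in groups[group] if t in set(seqs.ids)]
            if len(members) < 2:
                continue
            sub = seqs.subset(members)
            clustering = farthest_neighbor_cluster(pairwise_distance(sub), config.grid_step)
            clustering.check_nested()
            clusterings[group] = clustering
            for cutoff in clustering.cutoffs:
                partition = clustering.partition_at(cutoff)
                for rep, cluster_members in sorted(partition.items()):
                    for sid in cluster_members:
                        rows.append((group, float(cutoff), rep, sid))
                    list_lines.append(
                        f"{group}\t{cutoff:.3f}\t{len(partition)}\t" + ",".join(cluster_members)
                    )
        membership = pd.DataFrame(rows, columns=["group", "cutoff", "cluster_id", "sequence_id"])
        membership_path = stage_dir / "cluster_membership.tsv"
        membership.to_csv(membership_path, sep="\t", index=False)
        list_path = stage_dir / "clusters.list"
        list_path.write_text("\n".join(list_lines) + "\n")
        record("cluster", {"membership": membership_path, "list": list_path})

    if "scan" in config.stages:
        if not clusterings:
            raise RuntimeError("scan stage requires the cluster stage")
        stage_dir = out / "scan"
        stage_dir.mkdir(exist_ok=True)
        results = group_scan(clusterings, counts, metadata)
        pair_rows = []
        summary_rows = []
        for res in results:
            for _, row in res.pairs.iterrows():
                pair_rows.append(
                    (res.group, row["marine"], row["freshwater"], row["max_shared_identity"])
                )
            summary_rows.append(
                {
                    "group": res.group,
                    "evaluable": res.evaluable,
                    "n_marine_present": res.n_marine_present,
                    "n_freshwater_present": res.n_freshwater_present,
                    "n_pairs_skipped": res.n_pairs_skipped,
                    **res.summary,
                }
            )
        pairs_path = stage_dir / "scan_pairs.tsv"
        pd.DataFrame(
            pair_rows, columns=["group", "marine", "freshwater", "max_shared_identity"]
        ).to_csv(pairs_path, sep="\t", index=False)
        summary_path = stage_dir / "scan_summary.tsv"
        pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
        record("scan", {"pairs": pairs_path, "summary": summary_path})

    if "unifrac" in config.stages:
        stage_dir = out / "unifrac"
        stage_dir.mkdir(exist_ok=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rare = rarefy(counts, config.rarefaction_depth, seed=config.seed)
        if rare.shape[1] < 4:
            raise ValueError(
                f"only {rare.shape[1]} samples reach rarefaction depth "
                f"{config.rarefaction_depth}; lower the depth"
            )
        habitats = metadata.set_index("sample_id")["habitat"]
        dm = sample_pair_unifrac(tree, rare, weighted=False)
        dm_path = stage_dir / "unweighted_unifrac.tsv"
        dm.to_csv(dm_path, sep="\t")
        files = {"unweighted_matrix": dm_path}
        labels = [habitats[s] for s in dm.columns]
        f_stat, r2, p = permanova(dm, labels, n_perm=config.n_permutations, seed=config.seed)
        tests = [{"test": "permanova_unweighted", "F": f_stat, "R2": r2, "p": p}]
        if config.weighted:
            dmw = sample_pair_unifrac(tree, rare, weighted=True)
            dmw_path = stage_dir / "weighted_unifrac.tsv"
            dmw.to_csv(dmw_path, sep="\t")
            files["weighted_matrix"] = dmw_path
            f_w, r2_w, p_w = permanova(dmw, labels, n_perm=config.n_permutations, seed=config.seed)
            tests.append({"test": "permanova_weighted", "F": f_w, "R2": r2_w, "p": p_w})

        pooled = pooled_group_unifrac(tree, rare, metadata, lineage, config.group_rank)
        pooled_path = stage_dir / "pooled_group_unifrac.tsv"
        pooled.to_csv(pooled_path, sep="\t")
        files["pooled_groups"] = pooled_path

        retained, _ = filter_groups(
            rare,
            lineage,
            metadata,
            rank=config.group_rank,
            min_samples_per_habitat=config.min_samples_per_habitat,
            min_taxa=config.min_taxa,
            min_sequences=config.min_sequences,
        )
        null_rows = []
        groups = lineage_groups(lineage, config.group_rank)
        marine = [s for s in rare.columns if habitats[s] == "marine"]
        fresh = [s for s in rare.columns if habitats[s] == "freshwater"]
        for group in sorted(retained):
            taxa = [t for t in groups[group] if t in rare.index]
            sub = rare.loc[taxa]
            observed = pooled.loc[group, "pooled_unifrac"]
            presence = (sub.to_numpy() > 0).astype(np.int8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                draws = independent_swap_null(presence, config.n_nulls, seed=config.seed)
            assert (draws.sum(axis=1) == presence.sum(axis=0)).all()
            assert (draws.sum(axis=2) == presence.sum(axis=1)).all()
            m_idx = [list(rare.columns).index(s) for s in marine]
            f_idx = [list(rare.columns).index(s) for s in fresh]
            subtree = tree.shear(set(sub.index[presence.any(axis=1)]))
            null_values = []
            for draw in draws:
                pooled_m = {taxa[i] for i in np.nonzero(draw[:, m_idx].any(axis=1))[0]}
                pooled_f = {taxa[i] for i in np.nonzero(draw[:, f_idx].any(axis=1))[0]}
                if not pooled_m or not pooled_f:
                    continue
                null_values.append(unweighted_unifrac(subtree, pooled_m, pooled_f))
            z, p_raw, p_bonf = z_test(observed, null_values, n_groups=len(retained))
            null_rows.append(
                {
                    "group": group,
                    "observed": observed,
                    "null_mean": float(np.mean(null_values)),
                    "null_sd": float(np.std(null_values, ddof=1)),
                    "n_null": len(null_values),
                    "z": z,
                    "p": p_raw,
                    "p_bonferroni": p_bonf,
                }
            )
        nulls_path = stage_dir / "group_null_tests.tsv"
        pd.DataFrame(null_rows).to_csv(nulls_path, sep="\t", index=False)
        files["group_null_tests"] = nulls_path
        tests_path = stage_dir / "permanova.tsv"
        pd.DataFrame(tests).to_csv(tests_path, sep="\t", index=False)
        files["permanova"] = tests_path
        record("unifrac", files)

    if "shared" in config.stages:
        stage_dir = out / "shared"
        stage_dir.mkdir(exist_ok=True)
        report = find_shared_taxa(counts, metadata, lineage, rank=config.scan_rank)
        shared_path = stage_dir / "shared_taxa.tsv"
        report.per_group.assign(
            total_shared=report.n_shared,
            genera_with_2plus_shared=report.n_genera_with_2plus_shared,
        ).to_csv(shared_path, sep="\t")
        accum_rows = []
        for axis in ("freshwater", "marine"):
            curve = accumulation_curve(
                counts, metadata, axis_habitat=axis,
                n_orderings=config.n_orderings, seed=config.seed,
            )
            for i in range(curve.n_sites.size):
                accum_rows.append(
                    (
                        axis,
                        int(curve.n_sites[i]),
                        float(curve.mean_shared[i]),
                        float(curve.min_shared[i]),
                        float(curve.max_shared[i]),
                        float(curve.mean_fraction[i]),
                    )
                )
        accum_path = stage_dir / "accumulation.tsv"
        pd.DataFrame(
            accum_rows,
            columns=["axis_habitat", "n_sites", "mean_shared", "min_shared", "max_shared", "mean_fraction"],
        ).to_csv(accum_path, sep="\t", index=False)
        enrich = fold_enrichment(counts, lineage, metadata, rank=config.scan_rank)
        enrich_path = stage_dir / "fold_enrichment.tsv"
        enrich.to_csv(enrich_path, sep="\t")
        record("shared", {"shared": shared_path, "accumulation": accum_path, "enrichment": enrich_path})

    if "detect" in config.stages:
        stage_dir = out / "detect"
        stage_dir.mkdir(exist_ok=True)
        cfg = config.detect
        params = DetectionParams(
            population_density=cfg["population_density"],
            community_density=cfg["community_density"],
            library_size=cfg["library_size"],
        )
        payload = {
            "params": {
                "population_density": params.population_density,
                "community_density": params.community_density,
                "library_size": params.library_size,
            },
            "p_zero_reads": detection_probability(params, 0),
            "p_one_read": detection_probability(params, 1),
            "p_zero_reads_poisson": detection_probability_poisson(params, 0),
            "expected_appearances": {
                str(s): establishment_appearances(s)
                for s in cfg.get("selective_advantages", [0.1, 0.001])
            },
        }
        detect_path = stage_dir / "detection.json"
        detect_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        record("detect", {"detection": detect_path})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
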