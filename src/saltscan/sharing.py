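"""Shared-taxon identification, group filters, accumulation curves, enrichment.

A taxon is "shared" when it is observed (count > 0, unrarefied) in at least
one marine and at least one freshwater sample.  Accumulation curves show how
the shared-taxon count grows as sampling sites of one habitat are added in
random order while the full opposite-habitat site set is held fixed — the
question being whether sharing saturates or keeps climbing with effort.
Fold enrichment summarizes habitat preference as the log10 ratio of median
relative group abundances between habitats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from saltscan.unifrac import lineage_groups


def _habitat_samples(counts: pd.DataFrame, metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
    habitats = metadata.set_index("sample_id")["habitat"]
    missing = set(counts.columns) - set(habitats.index)
    if missing:
        raise KeyError(f"metadata missing samples: {sorted(missing)}")
    marine = [s for s in counts.columns if habitats[s] == "marine"]
    fresh = [s for s in counts.columns if habitats[s] == "freshwater"]
    return marine, fresh


@dataclass
class SharedTaxonReport:
    """Shared-taxon tallies per taxonomic group plus habitat-wide totals."""

    shared_taxa: list[str]
    per_group: pd.DataFrame  # n_shared, n_marine_total, n_freshwater_total, shared fractions
    n_genera_with_2plus_shared: int

    @property
    def n_shared(self) -> int:
        return len(self.shared_taxa)


def find_shared_taxa(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    lineage: pd.Series | None = None,
    rank: int = 1,
) -> SharedTaxonReport:
    """Flag taxa observed in both habitats of an unrarefied count table.

    Per-group totals count the taxa observed in each habitat within the
    group, and shared fractions divide the group's shared count by those
    habitat totals.  The genus tally counts genera containing at least two
    shared taxa (computed only when lineage is supplied).
    """
    marine, fresh = _habitat_samples(counts, metadata)
    in_marine = (counts[marine] > 0).any(axis=1)
    in_fresh = (counts[fresh] > 0).any(axis=1)
    shared = in_marine & in_fresh
    shared_taxa = list(counts.index[shared])
    groups = (
        lineage_groups(lineage, rank) if lineage is not None else {"all": list(counts.index)}
    )
    records = []
    for group, taxa in groups.items():
        taxa = [t for t in taxa if t in counts.index]
        n_m = int(in_marine.loc[taxa].sum())
        n_f = int(in_fresh.loc[taxa].sum())
        n_s = int(shared.loc[taxa].sum())
        records.append(
            (
                group,
                n_s,
                n_m,
                n_f,
                n_s / n_m if n_m else np.nan,
                n_s / n_f if n_f else np.nan,
            )
        )
    per_group = pd.DataFrame(
        records,
        columns=[
            "group",
            "n_shared",
            "n_marine_total",
            "n_freshwater_total",
            "shared_frac_marine",
            "shared_frac_freshwater",
        ],
    ).set_index("group")
    n_genera = 0
    if lineage is not None:
        genus = lineage_groups(lineage, 5)
        n_genera = sum(
            1 for taxa in genus.values() if int(shared.reindex(taxa).fillna(False).sum()) >= 2
        )
    return SharedTaxonReport(
        shared_taxa=shared_taxa, per_group=per_group, n_genera_with_2plus_shared=n_genera
    )


def filter_groups(
    counts: pd.DataFrame,
    lineage: pd.Series,
    metadata: pd.DataFrame,
    rank: int = 1,
    min_samples_per_habitat: int = 3,
    min_taxa: int = 5,
    min_sequences: int = 500,
) -> tuple[list[str], dict[str, list[str]]]:
    """Group-inclusion filter for per-group beta-diversity analyses.

    Samples whose total sequence count for a group falls below
    ``min_sequences`` are excluded for that group only.  A group is retained
    when, after that exclusion, it is present in at least
    ``min_samples_per_habitat`` samples of each habitat and contains at least
    ``min_taxa`` taxa.  Returns the retained group list and the per-group
    included-sample lists.
    """
    marine, fresh = _habitat_samples(counts, metadata)
    groups = lineage_groups(lineage, rank)
    retained = []
    included: dict[str, list[str]] = {}
    for group, taxa in groups.items():
        taxa = [t for t in taxa if t in counts.index]
        sub = counts.loc[taxa]
        totals = sub.sum(axis=0)
        ok_samples = [s for s in counts.columns if totals[s] >= min_sequences and (sub[s] > 0).any()]
        included[group] = ok_samples
        n_m = sum(1 for s in ok_samples if s in marine)
        n_f = sum(1 for s in ok_samples if s in fresh)
        n_taxa = int((sub[ok_samples].sum(axis=1) > 0).sum()) if ok_samples else 0
        if n_m >= min_samples_per_habitat and n_f >= min_samples_per_habitat and n_taxa >= min_taxa:
            retained.append(group)
    return retained, included


@dataclass
class AccumulationCurve:
    """Shared-taxon accumulation against sites sampled on one habitat axis."""

    axis_habitat: str
    n_sites: np.ndarray
    mean_shared: np.ndarray
    min_shared: np.ndarray
    max_shared: np.ndarray
    mean_fraction: np.ndarray  # shared / axis-habitat taxa observed so far


def accumulation_curve(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    group_taxa: list[str] | None = None,
    axis_habitat: str = "freshwater",
    n_orderings: int = 100,
    seed: int = 0,
) -> AccumulationCurve:
    """Accumulate shared taxa over random orderings of one habitat's sites.

    The opposite habitat's full site set is held fixed; sites of
    ``axis_habitat`` are added in ``n_orderings`` random orders, recording
    after each addition the number of taxa shared with the fixed pool and
    the shared fraction of the axis habitat's taxa observed so far.
    """
    if n_orderings < 1:
        raise ValueError("n_orderings must be >= 1")
    if axis_habitat not in ("marine", "freshwater"):
        raise ValueError("axis_habitat must be 'marine' or 'freshwater'")
    sub = counts if group_taxa is None else counts.loc[[t for t in group_taxa if t in counts.index]]
    marine, fresh = _habitat_samples(sub, metadata)
    axis_samples = fresh if axis_habitat == "freshwater" else marine
    pool_samples = marine if axis_habitat == "freshwater" else fresh
    if not axis_samples or not pool_samples:
        raise ValueError("both habitats need at least one site")
    sites = metadata.set_index("sample_id")["site"]
    axis_sites = sorted({sites[s] for s in axis_samples})
    # presence per site: OR over that site's samples
    presence = np.stack(
        [
            (sub[[s for s in axis_samples if sites[s] == site]] > 0).any(axis=1).to_numpy()
            for site in axis_sites
        ]
    )
    pool = (sub[pool_samples] > 0).any(axis=1).to_numpy()
    rng = np.random.default_rng(seed)
    n_sites = len(axis_sites)
    shared_curves = np.empty((n_orderings, n_sites))
    frac_curves = np.empty((n_orderings, n_sites))
    for r in range(n_orderings):
        order = rng.permutation(n_sites)
        seen = np.logical_or.accumulate(presence[order], axis=0)
        shared = (seen & pool).sum(axis=1)
        observed = seen.sum(axis=1)
        shared_curves[r] = shared
        with np.errstate(invalid="ignore"):
            frac_curves[r] = np.where(observed > 0, shared / np.maximum(observed, 1), 0.0)
    return AccumulationCurve(
        axis_habitat=axis_habitat,
        n_sites=np.arange(1, n_sites + 1),
        mean_shared=shared_curves.mean(axis=0),
        min_shared=shared_curves.min(axis=0),
        max_shared=shared_curves.max(axis=0),
        mean_fraction=frac_curves.mean(axis=0),
    )


def fold_enrichment(
    counts: pd.DataFrame,
    lineage: pd.Series,
    metadata: pd.DataFrame,
    rank: int = 1,
) -> pd.DataFrame:
    """Habitat fold enrichment per group at a taxonomic rank.

    For each group: median relative abundance (group reads / library size)
    across freshwater samples, across marine samples, and
    log10(median_freshwater / median_marine).  A zero median is replaced by a
    pseudo-abundance of half the smallest nonzero per-sample group relative
    abundance in the table, so the ratio stays finite; enrichment of +1
    means 10x higher median abundance in freshwater.
    """
    marine, fresh = _habitat_samples(counts, metadata)
    groups = lineage_groups(lineage, rank)
    rel = counts / counts.sum(axis=0)
    group_rel = pd.DataFrame(
        {g: rel.loc[[t for t in taxa if t in rel.index]].sum(axis=0) for g, taxa in groups.items()}
    ).T  # groups x samples
    nonzero = group_rel.to_numpy()
    nonzero = nonzero[nonzero > 0]
    pseudo = nonzero.min() / 2 if nonzero.size else np.nan
    records = []
    for group in group_rel.index:
        med_f = float(group_rel.loc[group, fresh].median())
        med_m = float(group_rel.loc[group, marine].median())
        used_pseudo = med_f == 0 or med_m == 0
        lf = med_f if med_f > 0 else pseudo
        lm = med_m if med_m > 0 else pseudo
        records.append((group, med_f, med_m, float(np.log10(lf / lm)), used_pseudo))
    return pd.DataFrame(
        records,
        columns=[
            "group",
            "median_rel_abund_freshwater",
            "median_rel_abund_marine",
            "log10_fold_change",
            "pseudo_abundance_used",
        ],
    ).set_index("group")
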