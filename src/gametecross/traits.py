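"""Per-individual crossover traits: count, interference distance, shuffling.

Three quantitative traits summarise each individual's male meiosis:

* **CC** — crossover count per chromatid, the mean over its nuclei of the
  genome-wide crossover count divided by the number of chromosomes.
* **ICD** — inter-crossover distance, the mean distance (in relative
  chromosome length) between successive crossovers on the same chromatid;
  larger values at a given count indicate stronger crossover interference.
* **ICS** — intrachromosomal shuffling, the probability that two random loci
  on the same chromosome are uncoupled by one meiosis:
  ``r_intra = sum_k 2 p_k (1 - p_k) L_k**2`` where ``p_k`` is the proportion
  of chromosome *k* inherited from one haplotype and ``L_k`` the chromosome's
  length as a fraction of the genome.

``p_k`` is computed over informative windows, the unit at which haplotype
origin is defined after aggregation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._codes import ORIGIN_A, ORIGIN_B
from .crossover import WindowTrack
from .genotype_io import MarkerMap

__all__ = ["icd", "ics", "build_trait_table"]


def icd(events: pd.DataFrame) -> pd.DataFrame:
    """All inter-crossover distances, one row per successive pair.

    Distances are computed within (nucleus, chromosome) between successive
    crossover positions in relative chromosome length; chromatids with fewer
    than two crossovers contribute nothing.
    """
    cols = ["individual_id", "nucleus_id", "chromosome"]
    if not len(events):
        return pd.DataFrame(columns=cols + ["distance_rel"])
    d = events.sort_values(cols + ["position_rel"], kind="mergesort").copy()
    d["distance_rel"] = d.groupby(cols, sort=False, observed=True)["position_rel"].diff()
    return d.dropna(subset=["distance_rel"])[cols + ["distance_rel"]].reset_index(drop=True)


def ics(track: WindowTrack, marker_map: MarkerMap) -> float:
    """Intrachromosomal shuffling of one gamete from its window labels.

    Chromosomes without informative windows are excluded from the sum (with a
    warning); their L_k weight is simply not contributed.
    """
    total = 0.0
    for chrom, labels in track.labels.items():
        n_a = int((labels == ORIGIN_A).sum())
        n_b = int((labels == ORIGIN_B).sum())
        if n_a + n_b == 0:
            import warnings

            warnings.warn(f"{track.nucleus_id}/{chrom}: no informative windows, excluded from ICS")
            continue
        p = n_a / (n_a + n_b)
        lk = marker_map.rel_length(chrom)
        total += 2.0 * p * (1.0 - p) * lk**2
    return total


def build_trait_table(
    events: pd.DataFrame,
    tracks_by_individual: dict[str, list[WindowTrack]],
    marker_map: MarkerMap,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One trait record per individual, ordered by individual id.

    ICD is null for individuals without any multi-crossover chromatid;
    individuals absent from the metadata get null group fields with a warning.
    """
    n_chrom = len(marker_map.chromosomes)
    dist = icd(events)
    dist_by_ind = dist.groupby("individual_id")["distance_rel"].mean() if len(dist) else pd.Series(dtype=float)
    counts = events.groupby("nucleus_id").size() if len(events) else pd.Series(dtype=int)

    rows = []
    for ind in sorted(tracks_by_individual):
        tracks = tracks_by_individual[ind]
        cc = float(
            np.mean([counts.get(t.nucleus_id, 0) / n_chrom for t in tracks])
        ) if tracks else float("nan")
        ics_vals = [ics(t, marker_map) for t in tracks]
        rows.append(
            {
                "individual_id": ind,
                "n_nuclei": len(tracks),
                "cc_per_chromatid": cc,
                "icd_mean": float(dist_by_ind[ind]) if ind in dist_by_ind.index else np.nan,
                "ics_mean": float(np.mean(ics_vals)) if ics_vals else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if meta is not None:
        meta_idx = meta.set_index("individual_id")
        missing = set(table["individual_id"]) - set(meta_idx.index)
        if missing:
            import warnings

            warnings.warn(f"no metadata for individual(s) {sorted(missing)[:5]}")
        for col in ("subpopulation", "treatment"):
            table[col] = table["individual_id"].map(meta_idx[col])
    else:
        table["subpopulation"] = pd.NA
        table["treatment"] = pd.NA
    cols = [
        "individual_id",
        "subpopulation",
        "treatment",
        "n_nuclei",
        "cc_per_chromatid",
        "icd_mean",
        "ics_mean",
    ]
    return table[cols]
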