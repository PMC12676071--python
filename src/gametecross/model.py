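"""Study-level model and results objects.

:class:`SinglePollenStudy` is built from the four study inputs (haploid
gamete matrix, diploid sporophyte matrix, marker map, sample metadata) and
its :meth:`~SinglePollenStudy.fit` runs the full analysis: QC, per-individual
haplotype phasing, haplotype-origin labelling, window aggregation, crossover
calling and trait computation. The returned :class:`SinglePollenResults`
carries the event table, trait table, QC report and diagnostics, and exposes
the group statistics (ANOVA/Tukey, landscapes and their comparison, allele
stacking) plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crossover import (
    CrossoverConfig,
    WindowTrack,
    aggregate_windows,
    call_crossovers,
    crossover_summary,
    events_to_frame,
)
from .genotype_io import (
    GenotypeMatrix,
    MarkerMap,
    QCReport,
    qc_filter,
    read_genotype_table,
    read_marker_map,
    read_metadata,
)
from .landscape_stats import (
    GroupEffects,
    Landscape,
    LandscapeComparison,
    StackingResult,
    allele_stacking,
    build_landscape,
    compare_landscapes,
    group_effects,
)
from .phasing import label_origins, phase_individual
from .traits import build_trait_table

__all__ = ["SinglePollenStudy", "SinglePollenResults"]


class SinglePollenStudy:
    """Crossover analysis of one single-pollen-nucleus genotyping study."""

    def __init__(
        self,
        gametes: GenotypeMatrix,
        nuclei_of: dict,
        marker_map: MarkerMap,
        diploid: GenotypeMatrix | None = None,
        meta: pd.DataFrame | None = None,
        config: CrossoverConfig | None = None,
        link_window: int = 2,
    ):
        self.gametes = gametes
        self.nuclei_of = dict(nuclei_of)
        self.marker_map = marker_map
        self.diploid = diploid
        self.meta = meta
        self.config = config or CrossoverConfig()
        self.link_window = link_window

    @classmethod
    def from_files(
        cls,
        gametes_path,
        diploid_path,
        map_path,
        lengths_path,
        meta_path=None,
        nuclei_path=None,
        config: CrossoverConfig | None = None,
        link_window: int = 2,
    ) -> "SinglePollenStudy":
        """Build a study from delimited text files.

        ``nuclei_path`` maps nucleus ids to individual ids (two columns); if
        omitted, nucleus ids of the form ``<individual>_<suffix>`` are
        grouped by everything before the final underscore.
        """
        gametes = read_genotype_table(gametes_path, "haploid")
        diploid = read_genotype_table(diploid_path, "diploid")
        marker_map = read_marker_map(map_path, lengths_path)
        meta = read_metadata(meta_path) if meta_path else None
        if nuclei_path:
            pairs = pd.read_csv(nuclei_path, dtype=str)
            nuclei_of: dict[str, list[str]] = {}
            for nuc, ind in zip(pairs["nucleus_id"], pairs["individual_id"]):
                nuclei_of.setdefault(ind, []).append(nuc)
        else:
            nuclei_of = {}
            for nuc in gametes.sample_ids:
                ind = nuc.rsplit("_", 1)[0]
                nuclei_of.setdefault(ind, []).append(nuc)
        return cls(gametes, nuclei_of, marker_map, diploid, meta, config, link_window)

    @classmethod
    def from_cohort(cls, cohort, config: CrossoverConfig | None = None, link_window: int = 2):
        """Build a study directly from a simulated :class:`Cohort`."""
        return cls(
            cohort.gametes,
            cohort.nuclei_of,
            cohort.marker_map,
            cohort.diploid,
            cohort.meta,
            config,
            link_window,
        )

    def fit(self) -> "SinglePollenResults":
        gamete_sets, qc_report = qc_filter(
            self.gametes, self.nuclei_of, self.diploid, self.marker_map
        )
        all_events = []
        tracks_by_ind: dict[str, list[WindowTrack]] = {}
        nuclei_rows = []
        unresolved = {}
        parents = {}
        for gs in gamete_sets:
            parent = phase_individual(gs, self.marker_map, link_window=self.link_window)
            parents[gs.individual_id] = parent
            unresolved[gs.individual_id] = parent.n_unresolved_links
            tracks = label_origins(gs, parent, self.config.window_fraction)
            wts = [aggregate_windows(t, self.config) for t in tracks]
            tracks_by_ind[gs.individual_id] = wts
            for wt in wts:
                all_events.extend(call_crossovers(wt, gs.individual_id, self.config))
                nuclei_rows.append({"individual_id": gs.individual_id, "nucleus_id": wt.nucleus_id})
        events = events_to_frame(all_events)
        nuclei = pd.DataFrame(nuclei_rows, columns=["individual_id", "nucleus_id"])
        per_nucleus, per_individual, res_stats = crossover_summary(
            events, nuclei, len(self.marker_map.chromosomes)
        )
        traits = build_trait_table(events, tracks_by_ind, self.marker_map, self.meta)
        return SinglePollenResults(
            study=self,
            qc_report=qc_report,
            events=events,
            nuclei=nuclei,
            per_nucleus=per_nucleus,
            per_individual=per_individual,
            traits=traits,
            resolution_stats=res_stats,
            window_tracks=tracks_by_ind,
            phased_parents=parents,
            unresolved_links=unresolved,
        )


@dataclass
class SinglePollenResults:
    """Fitted crossover analysis: events, traits, diagnostics and statistics."""

    study: SinglePollenStudy
    qc_report: QCReport
    events: pd.DataFrame
    nuclei: pd.DataFrame
    per_nucleus: pd.DataFrame
    per_individual: pd.DataFrame
    traits: pd.DataFrame
    resolution_stats: dict
    window_tracks: dict = field(repr=False, default_factory=dict)
    phased_parents: dict = field(repr=False, default_factory=dict)
    unresolved_links: dict = field(repr=False, default_factory=dict)

    # -- headline quantities -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return int(self.nuclei["individual_id"].nunique())

    @property
    def n_nuclei(self) -> int:
        return int(len(self.nuclei))

    @property
    def n_crossovers(self) -> int:
        return int(len(self.events))

    @property
    def mean_co_per_nucleus(self) -> float:
        return float(self.per_nucleus["n_crossovers"].mean())

    @property
    def mean_co_per_individual(self) -> float:
        return float(self.per_nucleus.groupby("individual_id")["n_crossovers"].sum().mean())

    @property
    def mean_cc_per_chromatid(self) -> float:
        return float(self.traits["cc_per_chromatid"].mean())

    # -- statistics ----------------------------------------------------------
    def group_effects(self, trait: str = "cc_per_chromatid", by=("subpopulation", "treatment")) -> GroupEffects:
        return group_effects(self.traits, trait, by)

    def landscape(self, subset: pd.Series | None = None, label: str = "") -> Landscape:
        """Landscape over all retained gametes, or a boolean per-nucleus subset."""
        if subset is None:
            events, n = self.events, self.n_nuclei
        else:
            keep = self.nuclei.loc[subset.to_numpy(), "nucleus_id"]
            events = self.events[self.events["nucleus_id"].isin(set(keep))]
            n = int(len(keep))
        return build_landscape(events, n, self.study.marker_map, self.study.config, label)

    def landscapes_by(self, column: str = "treatment") -> dict[str, Landscape]:
        """One landscape per level of a metadata column (e.g. treatment)."""
        level_of = self.traits.set_index("individual_id")[column]
        levels = self.nuclei["individual_id"].map(level_of)
        return {
            lvl: self.landscape(subset=(levels == lvl), label=str(lvl))
            for lvl in sorted(levels.dropna().unique())
        }

    def compare_landscapes(self, a: Landscape, b: Landscape) -> LandscapeComparison:
        return compare_landscapes(a, b)

    def allele_stacking(self, indicators: pd.DataFrame, trait: str = "cc_per_chromatid") -> StackingResult:
        return allele_stacking(self.traits, indicators, trait)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Single-pollen-nucleus crossover analysis",
            "========================================",
            f"Individuals retained          {self.n_individuals} (of {self.qc_report.n_individuals_in})",
            f"Nuclei retained               {self.n_nuclei} (of {self.qc_report.n_nuclei_in})",
            f"Crossovers called             {self.n_crossovers}",
            f"Mean crossovers / individual  {self.mean_co_per_individual:.2f}",
            f"Mean crossovers / nucleus     {self.mean_co_per_nucleus:.2f}",
            f"Mean CC per chromatid         {self.mean_cc_per_chromatid:.2f}",
        ]
        frac = self.resolution_stats.get("fraction_resolution_le_1")
        if frac == frac:  # not NaN
            lines.append(f"Events with resolution <= 1   {100 * frac:.1f}%")
        try:
            ls = self.landscape()
            lines.append(f"Genome-wide rate              {ls.genome_wide_rate:.3f} cM/Mb")
        except Exception:
            pass
        if self.traits["treatment"].notna().any():
            lines.append("")
            lines.append("Group means (CC per chromatid)")
            means = self.traits.groupby(["subpopulation", "treatment"], dropna=True)[
                "cc_per_chromatid"
            ].agg(["mean", "count"])
            lines.append(means.to_string())
            try:
                ge = self.group_effects()
                lines.append("")
                lines.append("Tukey HSD contrasts")
                lines.append(ge.tukey.to_string(index=False))
            except ValueError:
                pass
        return "\n".join(lines)

    def write_dir(self, outdir) -> None:
        """Write events, traits, per-nucleus counts and QC report as CSV.

        Events are also written BED-like with bp intervals spanning the two
        flanking window midpoints.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traits.to_csv(outdir / "traits.csv", index=False)
        self.per_nucleus.to_csv(outdir / "per_nucleus.csv", index=False)
        self.qc_report.removals.to_csv(outdir / "qc_removals.csv", index=False)
        ev = self.events.copy()
        if len(ev):
            wf = self.study.config.window_fraction
            lens = ev["chromosome"].map(self.study.marker_map.chrom_lengths_bp)
            ev["start_bp"] = ((ev["left_window"] + 0.5) * wf * lens).astype(int)
            ev["end_bp"] = ((ev["right_window"] + 0.5) * wf * lens).astype(int)
        ev.to_csv(outdir / "events.csv", index=False)
        tokens = {0: "A", 1: "B", -1: "."}
        win_rows = [
            {
                "individual_id": ind,
                "nucleus_id": wt.nucleus_id,
                "chromosome": chrom,
                "window": w,
                "label": tokens[int(lab)],
            }
            for ind, wts in self.window_tracks.items()
            for wt in wts
            for chrom, labels in wt.labels.items()
            for w, lab in enumerate(labels)
        ]
        pd.DataFrame(win_rows).to_csv(outdir / "window_tracks.csv", index=False)
        hap_rows = [
            {
                "individual_id": ind,
                "chromosome": chrom,
                "marker_id": m,
                "hap_a": tokens[int(a)],
                "hap_b": tokens[1 - int(a)],
                "phase_block": int(b),
            }
            for ind, parent in self.phased_parents.items()
            for chrom, pc in parent.chromosomes.items()
            for m, a, b in zip(pc.marker_ids, pc.hap_a, pc.block_ids)
        ]
        pd.DataFrame(hap_rows).to_csv(outdir / "phased_haplotypes.csv", index=False)
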