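"""Genotype, marker-map and metadata I/O plus the cohort quality-control filters.

Input tables are plain delimited text (comma or tab, auto-detected): genotype
matrices are samples x markers with a header row of marker ids and the sample
id in the first column; the marker map has columns ``marker_id, chromosome,
position_bp``; chromosome lengths are a two-column ``chromosome, length_bp``
table; sample metadata has columns ``individual_id, subpopulation, treatment``.

QC implements the cohort filters used for single-pollen-nucleus array data:
nuclei with an allele call rate below 10% are discarded, individuals retaining
fewer than three nuclei are discarded, and individuals whose retained nuclei
jointly exceed 50% missing data at their informative markers are discarded.
Thresholds are strict inequalities; boundary values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._codes import ALLELE_A, ALLELE_B, DEFAULT_ALPHABET, HET, MISSING

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "GameteSet",
    "QCReport",
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_map",
    "read_metadata",
    "qc_filter",
    "informative_markers",
]


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _natural_chrom_key(name: str):
    digits = "".join(c for c in name if c.isdigit())
    return (int(digits) if digits else 0, name)


class MarkerMap:
    """Marker coordinates on a genome with declared chromosome lengths.

    Markers are stored sorted by (chromosome, position_bp); positions are
    1-based and each marker carries its position as a fraction of its
    chromosome's length (``rel_position`` in (0, 1]).
    """

    def __init__(self, table: pd.DataFrame, chrom_lengths_bp: Mapping[str, int]):
        required = {"marker_id", "chromosome", "position_bp"}
        if not required.issubset(table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        tab = table.copy()
        missing_len = set(tab["chromosome"]) - set(chrom_lengths_bp)
        if missing_len:
            raise ValueError(f"no declared length for chromosome(s) {sorted(missing_len)}")
        if tab["marker_id"].duplicated().any():
            dup = tab.loc[tab["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicated marker ids: {dup[:5]}")
        order = sorted(chrom_lengths_bp, key=_natural_chrom_key)
        tab["chromosome"] = pd.Categorical(tab["chromosome"], categories=order, ordered=True)
        tab = tab.sort_values(["chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)
        tab["chrom_length_bp"] = tab["chromosome"].map(chrom_lengths_bp).astype(np.int64)
        if (tab["position_bp"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if (tab["position_bp"] > tab["chrom_length_bp"]).any():
            raise ValueError("marker position beyond declared chromosome length")
        tab["rel_position"] = tab["position_bp"] / tab["chrom_length_bp"]
        for chrom, sub in tab.groupby("chromosome", observed=True):
            if sub["position_bp"].duplicated().any():
                raise ValueError(f"non-unique positions on {chrom}")
        self.table = tab
        self.chrom_lengths_bp = {c: int(chrom_lengths_bp[c]) for c in order}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths_bp)

    @property
    def marker_chrom(self) -> dict:
        """marker_id -> chromosome (cached)."""
        if not hasattr(self, "_marker_chrom"):
            self._marker_chrom = dict(
                zip(self.table["marker_id"], self.table["chromosome"].astype(str))
            )
        return self._marker_chrom

    @property
    def marker_rel(self) -> dict:
        """marker_id -> relative position (cached)."""
        if not hasattr(self, "_marker_rel"):
            self._marker_rel = dict(zip(self.table["marker_id"], self.table["rel_position"]))
        return self._marker_rel

    @property
    def genome_length_bp(self) -> int:
        return sum(self.chrom_lengths_bp.values())

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]

    def rel_length(self, chrom: str) -> float:
        """Chromosome length as a fraction of total genome length (L_k)."""
        return self.chrom_lengths_bp[chrom] / self.genome_length_bp

    @classmethod
    def from_files(cls, map_path, lengths_path, delimiter: str | None = None) -> "MarkerMap":
        d1 = delimiter or _sniff_delimiter(map_path)
        tab = pd.read_csv(map_path, sep=d1, dtype={"marker_id": str, "chromosome": str})
        d2 = delimiter or _sniff_delimiter(lengths_path)
        lens = pd.read_csv(lengths_path, sep=d2, dtype={"chromosome": str})
        return cls(tab, dict(zip(lens["chromosome"], lens["length_bp"])))

    def to_files(self, map_path, lengths_path, delimiter: str = ",") -> None:
        self.table[["marker_id", "chromosome", "position_bp"]].to_csv(
            map_path, sep=delimiter, index=False
        )
        pd.DataFrame(
            {"chromosome": list(self.chrom_lengths_bp), "length_bp": list(self.chrom_lengths_bp.values())}
        ).to_csv(lengths_path, sep=delimiter, index=False)


@dataclass
class GenotypeMatrix:
    """A samples x markers call matrix, integer-coded (see ``_codes``)."""

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # (n_samples, n_markers) int8
    ploidy: str  # "haploid" | "diploid"

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError("call matrix shape inconsistent with ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicated marker ids")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError("ploidy must be 'haploid' or 'diploid'")
        if self.ploidy == "haploid" and (self.calls == HET).any():
            raise ValueError("heterozygous call in haploid matrix")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    def row(self, sample_id: str) -> np.ndarray:
        if sample_id not in self._sample_index:
            raise KeyError(f"sample {sample_id!r} not in matrix")
        return self.calls[self._sample_index[sample_id]]

    def call_rates(self) -> np.ndarray:
        """Per-sample fraction of non-missing calls over all assayed markers."""
        return (self.calls != MISSING).mean(axis=1)

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {m: j for j, m in enumerate(self.marker_ids)}
        cols = [idx[m] for m in marker_ids]
        return GenotypeMatrix(self.sample_ids, list(marker_ids), self.calls[:, cols], self.ploidy)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self._sample_index[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.marker_ids, self.calls[rows], self.ploidy)


def read_genotype_table(
    path,
    ploidy: str,
    alphabet: Mapping[str, int] | None = None,
    delimiter: str | None = None,
) -> GenotypeMatrix:
    """Read a delimited samples x markers genotype table.

    First column holds sample ids, header row holds marker ids. Tokens outside
    the alphabet (default ``{A, B, AB, NA}``) are a hard error, reported with
    their values; a heterozygous token in a haploid file is a hard error.
    """
    alphabet = dict(alphabet or DEFAULT_ALPHABET)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    tokens = df.to_numpy()
    codes = np.full(tokens.shape, MISSING, dtype=np.int8)
    seen = set(np.unique(tokens))
    unknown = seen - set(alphabet)
    if unknown:
        raise ValueError(f"unknown genotype token(s) {sorted(unknown)} in {path}")
    for tok, code in alphabet.items():
        codes[tokens == tok] = code
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), codes, ploidy)


def write_genotype_table(
    gm: GenotypeMatrix, path, alphabet: Mapping[str, int] | None = None, delimiter: str = ","
) -> None:
    alphabet = dict(alphabet or DEFAULT_ALPHABET)
    inv = {code: tok for tok, code in alphabet.items()}
    tokens = np.vectorize(inv.__getitem__)(gm.calls)
    pd.DataFrame(tokens, index=gm.sample_ids, columns=gm.marker_ids).to_csv(
        path, sep=delimiter, index_label="id"
    )


def read_marker_map(map_path, lengths_path, delimiter=None) -> MarkerMap:
    return MarkerMap.from_files(map_path, lengths_path, delimiter)


def read_metadata(path, delimiter=None) -> pd.DataFrame:
    sep = delimiter or _sniff_delimiter(path)
    meta = pd.read_csv(path, sep=sep, dtype=str)
    required = {"individual_id", "subpopulation", "treatment"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    if meta["individual_id"].duplicated().any():
        raise ValueError("duplicated individual_id in metadata")
    return meta


@dataclass
class GameteSet:
    """Retained nuclei of one individual, restricted to its informative markers."""

    individual_id: str
    nuclei_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # (n_nuclei, n_informative) int8, values in {A, B, MISSING}
    qc_flags: dict = field(default_factory=dict)  # nucleus -> {"call_rate": ...}

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei_ids)


@dataclass
class QCReport:
    removals: pd.DataFrame  # columns: unit, kind ("nucleus"|"individual"), reason, value
    n_nuclei_in: int = 0
    n_nuclei_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"QC: nuclei {self.n_nuclei_in} -> {self.n_nuclei_out}, "
            f"individuals {self.n_individuals_in} -> {self.n_individuals_out}, "
            f"{len(self.removals)} removals"
        )


def informative_markers(
    diploid: GenotypeMatrix, individual_id: str, marker_map: MarkerMap
) -> list[str]:
    """Markers heterozygous in the individual, in (chromosome, position) order.

    Only heterozygous sporophyte markers segregate among the gametes and are
    informative for phasing and crossover detection.
    """
    row = diploid.row(individual_id)  # KeyError if absent
    by_marker = dict(zip(diploid.marker_ids, row))
    ordered = [
        m for m in marker_map.marker_ids if by_marker.get(m, MISSING) == HET
    ]
    if not ordered:
        import warnings

        warnings.warn(f"individual {individual_id} has no heterozygous markers")
    return ordered


def qc_filter(
    gametes: GenotypeMatrix,
    nuclei_of: Mapping[str, Sequence[str]],
    diploid: GenotypeMatrix | None = None,
    marker_map: MarkerMap | None = None,
    min_call_rate: float = 0.10,
    max_missing: float = 0.50,
    min_nuclei: int = 3,
) -> tuple[list[GameteSet], QCReport]:
    """Apply the cohort QC filters and build per-individual gamete sets.

    Order of application: per-nucleus call rate (over all assayed markers,
    strict ``< min_call_rate`` removal), then the minimum nucleus count, then
    the joint missing-data fraction of the individual's retained nuclei at its
    informative markers (strict ``> max_missing`` removal). When no diploid
    matrix is supplied the informative restriction is skipped and the missing
    fraction uses all markers.
    """
    removals: list[dict] = []
    if gametes.calls.size == 0 or not nuclei_of:
        import warnings

        warnings.warn("qc_filter: empty input")
        return [], QCReport(pd.DataFrame(columns=["unit", "kind", "reason", "value"]))

    rates = dict(zip(gametes.sample_ids, gametes.call_rates()))
    out: list[GameteSet] = []
    n_nuc_in = sum(len(v) for v in nuclei_of.values())
    for ind in nuclei_of:
        nuclei = list(nuclei_of[ind])
        kept = []
        for nuc in nuclei:
            r = rates[nuc]
            if r < min_call_rate:
                removals.append(
                    {"unit": nuc, "kind": "nucleus", "reason": "call_rate", "value": float(r)}
                )
            else:
                kept.append(nuc)
        if len(kept) < min_nuclei:
            removals.append(
                {"unit": ind, "kind": "individual", "reason": "too_few_nuclei", "value": len(kept)}
            )
            continue
        if diploid is not None:
            if marker_map is None:
                raise ValueError("marker_map required when diploid genotypes are supplied")
            markers = informative_markers(diploid, ind, marker_map)
        else:
            markers = list(gametes.marker_ids)
        sub = gametes.subset_samples(kept).subset_markers(markers)
        miss = float((sub.calls == MISSING).mean()) if sub.calls.size else 1.0
        if miss > max_missing:
            removals.append(
                {"unit": ind, "kind": "individual", "reason": "missing_fraction", "value": miss}
            )
            continue
        out.append(
            GameteSet(
                individual_id=ind,
                nuclei_ids=kept,
                marker_ids=markers,
                calls=sub.calls,
                qc_flags={n: {"call_rate": float(rates[n])} for n in kept},
            )
        )
    report = QCReport(
        removals=pd.DataFrame(removals, columns=["unit", "kind", "reason", "value"]),
        n_nuclei_in=n_nuc_in,
        n_nuclei_out=sum(g.n_nuclei for g in out),
        n_individuals_in=len(nuclei_of),
        n_individuals_out=len(out),
    )
    return out, report
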