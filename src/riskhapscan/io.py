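"""Data model and readers/writers for phased genotypes, phenotypes, and IBD segments.

Coordinate conventions shared by every analysis stage:

* positions are 1-based inclusive (VCF convention), intervals inclusive on
  both ends;
* genetic positions come from a linear 1 cM/Mb map unless an explicit cM
  column is supplied;
* haplotype sides are numbered 1/2 in VCF GT order and never reordered.

Missing genotypes are rejected at load time: every downstream statistic
(shared tracts, EHH, IBD summaries) is undefined under missingness, and the
simulator emits complete data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "PhasedHaplotypeSet",
    "CohortTable",
    "IBDSegmentSet",
    "FocalMarkerSpec",
    "linear_genetic_map",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_ibd_segments",
    "write_ibd_segments",
    "read_phenotypes",
    "write_phenotypes",
    "dosage_at",
    "dosage_matrix",
]

_NUCLEOTIDES = frozenset("ACGT")

#: Owner-reported lineages -> broad lineage group.
LINEAGE_GROUPS = {
    "pet": "ShowPet",
    "show": "ShowPet",
    "sled-show": "ShowPet",
    "husky-mix": "ShowPet",
    "racing": "Working",
    "seppala": "Working",
}


def linear_genetic_map(position_bp):
    """Genetic position (cM) under the linear 1 cM/Mb map: ``cM = bp / 1e6``.

    Accepts scalars or arrays; negative positions are rejected.
    """
    pos = np.asarray(position_bp, dtype=float)
    if np.any(pos < 0):
        raise ValueError("base-pair positions must be non-negative")
    out = pos / 1e6
    return float(out) if np.isscalar(position_bp) else out


@dataclass
class MarkerMap:
    """Marker positions and alleles for one chromosome region.

    ``position_cM`` defaults to the linear 1 cM/Mb map when not supplied.
    """

    marker_id: np.ndarray
    chromosome: str
    position_bp: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    position_cM: np.ndarray = field(default=None)
    map_source: str = "linear-1cM/Mb"

    def __post_init__(self):
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        if self.position_cM is None:
            self.position_cM = linear_genetic_map(self.position_bp)
        else:
            self.position_cM = np.asarray(self.position_cM, dtype=float)
        if np.any(np.diff(self.position_bp) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        for a in np.concatenate([self.ref_allele, self.alt_allele]):
            if a not in _NUCLEOTIDES:
                raise ValueError(f"allele {a!r} is not one of A/C/G/T")
        self._index = {m: i for i, m in enumerate(self.marker_id)}

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in map") from None


@dataclass
class PhasedHaplotypeSet:
    """H x M matrix of 0/1 allele codes (0 = ref, 1 = alt), two rows per dog.

    ``haplotype_ids`` is a list of ``(dog_id, side)`` with side in {1, 2},
    in VCF GT order.
    """

    haplotype_ids: list
    alleles: np.ndarray
    map: MarkerMap

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        h, m = self.alleles.shape
        if h != len(self.haplotype_ids):
            raise ValueError("row count does not match haplotype ids")
        if m != self.map.n_markers:
            raise ValueError("column count does not match marker map")
        if h % 2:
            raise ValueError("haplotype count must be even (two per dog)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele codes must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def dog_ids(self) -> list:
        return [d for d, s in self.haplotype_ids[::2]]


@dataclass
class FocalMarkerSpec:
    """Lead risk marker, its risk allele, and the summary interval around it."""

    marker_id: str
    risk_allele: str
    interval_start_bp: int
    interval_end_bp: int

    def validate(self, mm: MarkerMap) -> int:
        idx = mm.index_of(self.marker_id)
        if self.risk_allele not in (mm.ref_allele[idx], mm.alt_allele[idx]):
            raise ValueError(
                f"risk allele {self.risk_allele!r} matches neither allele of "
                f"{self.marker_id}"
            )
        pos = mm.position_bp[idx]
        if not (self.interval_start_bp <= pos <= self.interval_end_bp):
            raise ValueError("summary interval does not contain the focal marker")
        return idx

    def risk_code(self, mm: MarkerMap) -> int:
        """0/1 allele code of the risk allele at the focal column."""
        idx = mm.index_of(self.marker_id)
        return 1 if self.risk_allele == mm.alt_allele[idx] else 0


def dosage_matrix(haps: PhasedHaplotypeSet) -> np.ndarray:
    """Per-dog alt-allele dosage (0/1/2) over all markers, dogs x markers."""
    return (haps.alleles[0::2].astype(np.int64) + haps.alleles[1::2])


def dosage_at(haps: PhasedHaplotypeSet, focal: FocalMarkerSpec) -> np.ndarray:
    """Per-dog risk-allele dosage (0, 1, or 2 copies) at the focal marker."""
    idx = focal.validate(haps.map)
    col = haps.alleles[:, idx].astype(np.int64)
    if focal.risk_code(haps.map) == 0:
        col = 1 - col
    return col[0::2] + col[1::2]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path) -> tuple[MarkerMap, PhasedHaplotypeSet]:
    """Read a phased VCF of biallelic A/C/G/T SNPs into the data model.

    Unphased genotypes, missing calls, multiallelic sites, and non-ACGT
    allele codes are rejected with the offending site named.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    ids, pos, refs, alts = [], [], [], []
    columns = []
    chrom = None
    for v in vcf:
        site = f"{v.CHROM}:{v.POS}"
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise ValueError(f"multiple chromosomes in VCF (site {site})")
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic site at {site}")
        if v.REF not in _NUCLEOTIDES or v.ALT[0] not in _NUCLEOTIDES:
            raise ValueError(f"non-ACGT allele at {site}: {v.REF}>{v.ALT}")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {site} (sample {samples[i]})")
            if not phased:
                raise ValueError(f"unphased genotype at {site} (sample {samples[i]})")
            col[2 * i] = a
            col[2 * i + 1] = b
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        pos.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        columns.append(col)
    if not columns:
        raise ValueError("VCF contains no sites")
    mm = MarkerMap(ids, chrom, pos, refs, alts)
    alleles = np.stack(columns, axis=1)
    hap_ids = [(s, side) for s in samples for side in (1, 2)]
    return mm, PhasedHaplotypeSet(hap_ids, alleles, mm)


def write_phased_vcf(path, mm: MarkerMap, haps: PhasedHaplotypeSet) -> None:
    """Write the data model as a minimal phased VCF 4.2 text file."""
    dogs = haps.dog_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={mm.chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(d) for d in dogs)
            + "\n"
        )
        a = haps.alleles
        for j in range(mm.n_markers):
            gts = "\t".join(
                f"{a[2 * i, j]}|{a[2 * i + 1, j]}" for i in range(len(dogs))
            )
            fh.write(
                f"{mm.chromosome}\t{mm.position_bp[j]}\t{mm.marker_id[j]}\t"
                f"{mm.ref_allele[j]}\t{mm.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# IBD segments (hap-IBD output dialect)
# ---------------------------------------------------------------------------

@dataclass
class IBDSegmentSet:
    """Pairwise shared segments; pair ordering is canonicalized.

    Backed by a DataFrame with columns ``dog_a, side_a, dog_b, side_b,
    chromosome, start_bp, end_bp, length_cM``.
    """

    segments: pd.DataFrame

    COLUMNS = (
        "dog_a", "side_a", "dog_b", "side_b",
        "chromosome", "start_bp", "end_bp", "length_cM",
    )

    def __post_init__(self):
        df = self.segments.reset_index(drop=True).copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"IBD segment table missing columns {sorted(missing)}")
        if len(df) and (df.start_bp > df.end_bp).any():
            raise ValueError("IBD segment with start_bp > end_bp")
        if len(df) and (df.length_cM < 0).any():
            raise ValueError("negative IBD segment length")
        # canonical unordered pairs: (dog, side) lexicographically sorted
        a = list(zip(df.dog_a.astype(str), df.side_a.astype(int)))
        b = list(zip(df.dog_b.astype(str), df.side_b.astype(int)))
        swap = [x > y for x, y in zip(a, b)]
        if any(swap):
            sw = np.asarray(swap)
            for ca, cb in (("dog_a", "dog_b"), ("side_a", "side_b")):
                tmp = df.loc[sw, ca].copy()
                df.loc[sw, ca] = df.loc[sw, cb]
                df.loc[sw, cb] = tmp
        self.segments = df

    def __len__(self) -> int:
        return len(self.segments)


def read_ibd_segments(path, marker_map: MarkerMap | None = None) -> IBDSegmentSet:
    """Read a hap-IBD-style TSV: sample1, hap1, sample2, hap2, chrom, start, end[, cM].

    No header is expected (hap-IBD emits none). When the length column is
    absent, length_cM is recomputed from the linear genetic map.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (7, 8):
                raise ValueError(
                    f"{path}: line {lineno}: expected 7 or 8 tab-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                rec = dict(
                    dog_a=parts[0], side_a=int(parts[1]),
                    dog_b=parts[2], side_b=int(parts[3]),
                    chromosome=parts[4],
                    start_bp=int(parts[5]), end_bp=int(parts[6]),
                )
                if len(parts) == 8:
                    rec["length_cM"] = float(parts[7])
                else:
                    rec["length_cM"] = linear_genetic_map(
                        rec["end_bp"] - rec["start_bp"]
                    )
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from None
            rows.append(rec)
    df = pd.DataFrame(rows, columns=list(IBDSegmentSet.COLUMNS))
    return IBDSegmentSet(df)


def write_ibd_segments(path, segs: IBDSegmentSet) -> None:
    """Write segments in the 8-column headerless hap-IBD dialect."""
    segs.segments.to_csv(
        path, sep="\t", header=False, index=False,
        columns=list(IBDSegmentSet.COLUMNS),
    )


# ---------------------------------------------------------------------------
# Phenotype / covariate table
# ---------------------------------------------------------------------------

#: Columns every phenotype table must provide.
_REQUIRED_PHENO = (
    "dog_id", "status", "sex", "lineage", "cohort_label",
    "age_last_followup_years", "gonadal_status",
)
_OPTIONAL_PHENO = ("age_onset_years", "age_gonadectomy_years")


@dataclass
class CohortTable:
    """Per-dog phenotype/covariate table with derived lineage grouping.

    Invariants enforced on construction: controls carry no onset age; case
    onset age never exceeds last follow-up; gonadectomized dogs have a
    gonadectomy age. Extra numeric columns (e.g. PC1..PC5) ride along as
    covariates.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.reset_index(drop=True).copy()
        missing = set(_REQUIRED_PHENO) - set(df.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        for col in _OPTIONAL_PHENO:
            if col not in df.columns:
                df[col] = np.nan
        df["dog_id"] = df["dog_id"].astype(str)
        if df["dog_id"].duplicated().any():
            raise ValueError("duplicate dog_id in phenotype table")
        bad = ~df["status"].isin(["case", "control"])
        if bad.any():
            raise ValueError(f"invalid status values: {sorted(df.status[bad].unique())}")
        if not df["sex"].isin(["M", "F"]).all():
            raise ValueError("sex must be M or F")
        badlin = ~df["lineage"].isin(LINEAGE_GROUPS)
        if badlin.any():
            raise ValueError(
                f"unknown lineage values: {sorted(df.lineage[badlin].unique())}"
            )
        df["lineage_group"] = df["lineage"].map(LINEAGE_GROUPS)
        if not df["gonadal_status"].isin(["intact", "gonadectomized"]).all():
            raise ValueError("gonadal_status must be intact or gonadectomized")
        ctrl = df["status"] == "control"
        if df.loc[ctrl, "age_onset_years"].notna().any():
            bad_ids = df.loc[ctrl & df.age_onset_years.notna(), "dog_id"].tolist()
            raise ValueError(f"control rows with onset age: {bad_ids}")
        case = ~ctrl
        onset = df.loc[case, "age_onset_years"]
        fup = df.loc[case, "age_last_followup_years"]
        if ((onset - fup) > 1e-9).any():
            raise ValueError("case with onset age after last follow-up")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def covariate_columns(self) -> list:
        known = set(_REQUIRED_PHENO) | set(_OPTIONAL_PHENO) | {"lineage_group"}
        return [
            c for c in self.table.columns
            if c not in known and pd.api.types.is_numeric_dtype(self.table[c])
        ]

    def cases_missing_onset(self) -> list:
        """Dog ids of cases lacking an onset age (flagged for onset analyses)."""
        df = self.table
        m = (df.status == "case") & df.age_onset_years.isna()
        return df.loc[m, "dog_id"].tolist()


def read_phenotypes(path) -> CohortTable:
    """Read a comma- or tab-delimited phenotype table (header required)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return CohortTable(df)


def write_phenotypes(path, cohort: CohortTable) -> None:
    cohort.table.drop(columns=["lineage_group"]).to_csv(path, index=False)
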