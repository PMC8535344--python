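"""Standard file formats and run records.

Genotypes travel as PED/MAP (linkage format): whitespace-delimited PED rows
with six leading columns (family, individual, father, mother, sex, affection)
followed by two allele columns per mapped marker, allele code ``0`` meaning
missing.  Phenotypes are plain CSV.  Scan results are written as TSV reports.
Every CLI run can be accompanied by a JSON run record (seed, parameters, input
file hashes) so that permutation results are replayable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("sibscan")

MISSING = -1  # dosage code for a missing call
VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input parsed but violated a domain constraint."""


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered SNP map with the two alleles seen at each marker.

    ``table`` columns: marker_id, chromosome, position_bp (1-based physical),
    allele_a, allele_b.  allele_a < allele_b alphabetically when both are
    known; allele_b is None for a marker observed monomorphic.  Positions are
    strictly increasing within each chromosome and marker ids are unique.
    Intervals between markers are treated as closed ``[start_bp, end_bp]``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position_bp", "allele_a", "allele_b"}
        missing_cols = required - set(self.table.columns)
        if missing_cols:
            raise ValidationError(f"marker map missing columns: {sorted(missing_cols)}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate marker id {dup!r}")
        for _, sub in self.table.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError("positions not strictly increasing within chromosome")
        for _, row in self.table.iterrows():
            if row.allele_b is not None and row.allele_a == row.allele_b:
                raise ValidationError(f"marker {row.marker_id}: identical alleles")

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def index_of(self, marker_id: str) -> int:
        idx = self.table.index[self.table["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(idx[0])

    def alleles(self, marker_id: str) -> tuple[str, str | None]:
        row = self.table.iloc[self.index_of(marker_id)]
        return row.allele_a, row.allele_b


def marker_map_from_arrays(marker_ids, positions_bp, allele_a, allele_b,
                           chromosome: str = "16") -> MarkerMap:
    """Build a MarkerMap from parallel sequences (convenience for simulation)."""
    return MarkerMap(pd.DataFrame({
        "marker_id": list(marker_ids),
        "chromosome": chromosome,
        "position_bp": list(positions_bp),
        "allele_a": list(allele_a),
        "allele_b": list(allele_b),
    }))


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Unphased diploid calls for samples x markers.

    ``dosage[i, j]`` counts copies of ``allele_b`` of marker j carried by
    sample i (0, 1 or 2) or :data:`MISSING`.  Because every non-missing call
    uses only the marker's two alleles, the dosage encoding is lossless.
    ``pedigree`` (optional) carries the six leading PED columns.
    """

    sample_ids: list[str]
    markers: MarkerMap
    dosage: np.ndarray
    pedigree: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), self.markers.n_markers):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {self.markers.n_markers} markers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if bad.any():
            raise ValidationError("dosage values outside {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from exc

    def call(self, sample_id: str, marker_id: str) -> tuple[str, str] | None:
        """The unordered allele pair, or None if missing."""
        i = self.sample_ids.index(sample_id)
        j = self.markers.index_of(marker_id)
        d = int(self.dosage[i, j])
        if d == MISSING:
            return None
        a, b = self.markers.alleles(marker_id)
        return tuple(sorted([a] * (2 - d) + [str(b)] * d))  # type: ignore[return-value]

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        ped = None
        if self.pedigree is not None:
            ped = (self.pedigree.set_index("sample_id").loc[list(sample_ids)]
                   .reset_index())
        return GenotypeMatrix(list(sample_ids), self.markers,
                              self.dosage[idx], pedigree=ped)

    def allele_b_frequency(self, marker_id: str) -> float:
        """Frequency of allele_b among non-missing calls (NaN if none)."""
        j = self.markers.index_of(marker_id)
        col = self.dosage[:, j]
        called = col != MISSING
        n = int(called.sum())
        if n == 0:
            return float("nan")
        return float(col[called].sum()) / (2 * n)

    def minor_allele_frequency(self, marker_id: str) -> float:
        f = self.allele_b_frequency(marker_id)
        return min(f, 1.0 - f) if f == f else float("nan")


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_map(map_path) -> pd.DataFrame:
    """Read a linkage .map file: chromosome, marker_id, genetic pos, bp."""
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{map_path}: line {ln}: expected 4 columns, got {len(parts)}")
            rows.append((parts[0], parts[1], int(parts[3])))
    df = pd.DataFrame(rows, columns=["chromosome", "marker_id", "position_bp"])
    return df


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read unphased genotypes from PED/MAP.

    Alleles for each marker are inferred from the observed calls (the map
    file does not carry them); a marker with more than two observed alleles
    is a format error.  Sample order is preserved; allele code ``0`` becomes
    a missing call.
    """
    map_df = read_map(map_path)
    n_markers = len(map_df)
    ped_rows = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}: row {ln}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} mapped markers, got {len(parts)}")
            for tok in parts[6:]:
                if tok not in VALID_ALLELES and tok != "0":
                    raise FormatError(
                        f"{ped_path}: row {ln}: invalid allele code {tok!r}")
            ped_rows.append(parts[:6])
            allele_pairs.append([(parts[6 + 2 * j], parts[7 + 2 * j])
                                 for j in range(n_markers)])
    n_samples = len(ped_rows)
    # infer the two alleles per marker
    allele_a, allele_b = [], []
    for j in range(n_markers):
        seen = sorted({a for pair in (row[j] for row in allele_pairs)
                       for a in pair if a != "0"})
        if len(seen) > 2:
            raise FormatError(
                f"marker {map_df.marker_id[j]}: more than two alleles observed: {seen}")
        if len(seen) == 2:
            allele_a.append(seen[0]); allele_b.append(seen[1])
        elif len(seen) == 1:
            allele_a.append(seen[0]); allele_b.append(None)
        else:
            allele_a.append("N"); allele_b.append(None)
    dosage = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    for i, row in enumerate(allele_pairs):
        for j, (x, y) in enumerate(row):
            if x == "0" or y == "0":
                if x != y:
                    raise FormatError(
                        f"{ped_path}: sample row {i + 1}, marker "
                        f"{map_df.marker_id[j]}: half-missing call {x}/{y}")
                continue
            dosage[i, j] = (x == allele_b[j]) + (y == allele_b[j])
    markers = MarkerMap(pd.DataFrame({
        "marker_id": map_df.marker_id, "chromosome": map_df.chromosome,
        "position_bp": map_df.position_bp,
        "allele_a": allele_a, "allele_b": allele_b}))
    pedigree = pd.DataFrame(
        ped_rows, columns=["family_id", "sample_id", "father", "mother", "sex", "affection"])
    if pedigree["sample_id"].duplicated().any():
        raise FormatError(f"{ped_path}: duplicate individual ids")
    return GenotypeMatrix(pedigree["sample_id"].tolist(), markers, dosage,
                          pedigree=pedigree)


def write_ped_map(genotypes: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP; inverse of :func:`read_ped_map` for calls/order."""
    mt = genotypes.markers.table
    with open(map_path, "w") as fh:
        for _, row in mt.iterrows():
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n")
    ped = genotypes.pedigree
    if ped is None:
        ped = pd.DataFrame({
            "family_id": genotypes.sample_ids, "sample_id": genotypes.sample_ids,
            "father": "0", "mother": "0", "sex": "0", "affection": "2"})
    ped = ped.set_index("sample_id").loc[genotypes.sample_ids].reset_index()
    a = mt["allele_a"].to_numpy()
    b = np.array([x if x is not None else "0" for x in mt["allele_b"]])
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            row = ped.iloc[i]
            cols = [row.family_id, sid, row.father, row.mother,
                    str(row.sex), str(row.affection)]
            for j in range(genotypes.markers.n_markers):
                d = genotypes.dosage[i, j]
                if d == MISSING:
                    cols += ["0", "0"]
                else:
                    cols += [b[j] if k < d else a[j] for k in range(2)]
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["sample_id", "family_id", "weight_pct_pred",
                     "fev1_centile", "birth_year"]


@dataclass
class PhenotypeTable:
    """Per-patient severity phenotypes.

    ``data`` columns: sample_id, family_id, weight_pct_pred (weight as % of
    predicted weight-for-height), fev1_centile (CF-population centile of
    FEV1%pred, in [0, 100]), birth_year, optionally sex.  ``rejects`` lists
    (row_index, reason) for input rows that could not be typed; input row
    count always equals ``len(data) + len(rejects)``.
    """

    data: pd.DataFrame
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(PHENOTYPE_COLUMNS) - set(self.data.columns)
        if missing:
            raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
        cent = self.data["fev1_centile"].to_numpy(dtype=float)
        ok = np.isnan(cent) | ((cent >= 0) & (cent <= 100))
        if not ok.all():
            bad = self.data["sample_id"].to_numpy()[~ok][0]
            raise ValidationError(f"sample {bad}: fev1_centile outside [0, 100]")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def families(self) -> dict[str, list[str]]:
        return {fam: sub["sample_id"].tolist()
                for fam, sub in self.data.groupby("family_id", sort=True)}

    def sib_pairs(self) -> dict[str, tuple[str, str]]:
        """family_id -> (sib1, sib2); every family must have exactly 2 samples."""
        out = {}
        for fam, sids in self.families().items():
            if len(sids) != 2:
                raise ValidationError(
                    f"family {fam}: {len(sids)} samples, sib-pair input needs exactly 2")
            out[fam] = (sids[0], sids[1])
        return out


def read_phenotype_table(csv_path) -> PhenotypeTable:
    """Read the phenotype CSV; unparsable numeric rows become rejects."""
    raw = pd.read_csv(csv_path, dtype=str)
    missing = set(PHENOTYPE_COLUMNS) - set(raw.columns)
    if missing:
        raise FormatError(f"{csv_path}: missing required columns {sorted(missing)}")
    rows, rejects = [], []
    for idx, row in raw.iterrows():
        try:
            rec = {
                "sample_id": str(row["sample_id"]),
                "family_id": str(row["family_id"]),
                "weight_pct_pred": float(row["weight_pct_pred"]),
                "fev1_centile": float(row["fev1_centile"]),
                "birth_year": int(float(row["birth_year"])),
            }
        except (TypeError, ValueError) as exc:
            rejects.append((int(idx), str(exc)))
            continue
        if "sex" in raw.columns:
            rec["sex"] = row["sex"]
        rows.append(rec)
    if rejects:
        logger.warning("%s: rejected %d rows with unparsable numerics",
                       csv_path, len(rejects))
    data = pd.DataFrame(rows)
    if data.empty:
        data = pd.DataFrame(columns=PHENOTYPE_COLUMNS)
    return PhenotypeTable(data=data, rejects=rejects)


def write_phenotype_table(table: PhenotypeTable, csv_path) -> None:
    table.data.to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# Scan reports
# ---------------------------------------------------------------------------

def write_scan_report(result, path) -> None:
    """TSV report: one row per tested window plus a Pbest/Pcorr summary row.

    Numbers are serialized with 10 significant digits so the report
    round-trips p-values well below 1e-10 relative error.
    """
    with open(path, "w") as fh:
        fh.write("window\tadjacent\tcontrast\tstatistic\tpraw\n")
        for w in result.window_results:
            fh.write("%s\t%s\t%s\t%.10g\t%.10g\n" % (
                "-".join(w.window), int(w.adjacent), result.contrast.name,
                w.statistic, w.praw))
        pcorr = "NA" if result.pcorr is None else "%.10g" % result.pcorr
        fh.write("#summary\tpbest=%.10g\tpcorr=%s\tn_permutations=%s\tseed=%s\n" % (
            result.pbest, pcorr,
            result.n_permutations if result.n_permutations else "NA",
            result.seed if result.seed is not None else "NA"))


def read_scan_report(path) -> tuple[pd.DataFrame, dict]:
    """Read back a scan report: (window rows, summary dict)."""
    rows, summary = [], {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if line.startswith("#summary"):
                for tok in line.rstrip("\n").split("\t")[1:]:
                    k, v = tok.split("=", 1)
                    summary[k] = v
                continue
            rows.append(line.rstrip("\n").split("\t"))
    df = pd.DataFrame(rows, columns=header)
    df["statistic"] = df["statistic"].astype(float)
    df["praw"] = df["praw"].astype(float)
    df["adjacent"] = df["adjacent"].astype(int).astype(bool)
    return df, summary


# ---------------------------------------------------------------------------
# Run records
# ---------------------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_record(path, *, command: str, seed: int | None,
                     parameters: dict, input_files: dict | None = None) -> None:
    """JSON record making a run (notably its permutations) replayable."""
    record = {
        "command": command,
        "seed": seed,
        "parameters": parameters,
        "input_hashes": {name: file_sha256(p)
                         for name, p in (input_files or {}).items()
                         if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
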