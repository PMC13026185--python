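"""CSV/JSON interchange formats.

Replicate tables are long CSVs (``sample_id,locus,replicate,allele1,allele2``,
0 = missing/failed); consensus genotypes round-trip through a wide
GenAlEx-style table with two columns per locus and 0 for missing data.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .consensus import ReplicateRecord, ReplicateTable
from .diet import DietReadTable
from .identity import Individual

REPLICATE_HEADER = ["sample_id", "locus", "replicate", "allele1", "allele2"]


def read_replicate_table(path) -> ReplicateTable:
    """Read and validate the long replicate CSV (0 encodes a failed PCR)."""
    records: List[ReplicateRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != REPLICATE_HEADER:
            raise ValueError(f"{path}: expected header {REPLICATE_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            sid, locus, rep_s, a1_s, a2_s = row
            try:
                rep, a1, a2 = int(rep_s), int(a1_s), int(a2_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if (a1 == 0) != (a2 == 0):
                raise ValueError(f"{path}:{lineno}: half-missing allele pair")
            alleles = None if a1 == 0 else tuple(sorted((a1, a2)))
            try:
                records.append(ReplicateRecord(sid, locus, rep, alleles))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return ReplicateTable(records)


def write_replicate_table(table: ReplicateTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPLICATE_HEADER)
        for r in sorted(table.records, key=lambda r: (r.sample_id, r.locus, r.replicate)):
            a1, a2 = r.alleles if r.alleles is not None else (0, 0)
            writer.writerow([r.sample_id, r.locus, r.replicate, a1, a2])


def write_genalex(individuals: Sequence[Individual], loci: Sequence[str], path) -> None:
    """Wide table: one row per individual, two columns per locus, 0 missing."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["individual", "sex"]
        for loc in loci:
            header += [loc, f"{loc}.2"]
        writer.writerow(header)
        for ind in individuals:
            row = [ind.individual_id, ind.sex]
            for loc in loci:
                call = ind.genotype.get(loc)
                row += [0, 0] if call is None else list(call)
            writer.writerow(row)


def read_genalex(path) -> List[Individual]:
    individuals = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        loci = [h for h in header[2:] if not h.endswith(".2")]
        for row in reader:
            if not row:
                continue
            geno = {}
            for i, loc in enumerate(loci):
                a1, a2 = int(row[2 + 2 * i]), int(row[3 + 2 * i])
                if a1 != 0:
                    geno[loc] = tuple(sorted((a1, a2)))
            individuals.append(Individual(
                individual_id=row[0], sex=row[1], genotype=geno))
    return individuals


DIET_HEADER = ["sample_id", "replicate", "taxon", "reads"]


def read_diet_table(path, sample_to_individual: Optional[Dict[str, str]] = None,
                    individual_sex: Optional[Dict[str, str]] = None) -> DietReadTable:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != DIET_HEADER:
            raise ValueError(f"{path}: expected header {DIET_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                records.append((row[0], int(row[1]), row[2], int(row[3])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
    return DietReadTable(records=records,
                         sample_to_individual=sample_to_individual or {},
                         individual_sex=individual_sex or {})


def write_diet_table(table: DietReadTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DIET_HEADER)
        for rec in sorted(table.records):
            writer.writerow(list(rec))


def read_locus_metadata(path) -> Dict[str, int]:
    """CSV locus,repeat_unit -> per-locus repeat-unit sizes in bp."""
    out = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["locus", "repeat_unit"]:
            raise ValueError(f"{path}: expected header locus,repeat_unit")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                out[row[0]] = int(row[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
    return out


def write_locus_metadata(units: Dict[str, int], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["locus", "repeat_unit"])
        for loc in sorted(units):
            writer.writerow([loc, units[loc]])


def write_truth(truth: Dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def read_truth(path) -> Dict:
    return json.loads(Path(path).read_text())
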