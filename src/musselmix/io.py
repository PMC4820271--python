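"""File I/O: Genepop reader/writer, the tabular genotype dialect, and
registry config files.

Genepop is the classic line-oriented text format for multilocus
co-dominant genotype data: a title line, one locus name per line (or a
single comma-separated line), then ``POP`` blocks, each line holding
``individual_id ,  0101 0102 ...`` with 2- or 3-digit allele codes; an
all-zero code means a missing genotype.

The tabular dialect is one TSV row per individual with columns
``id, sample, site, substrate`` followed by one column per locus holding
``a1/a2`` (``./.`` for missing).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .genotypes import SUBSTRATES, AlleleRegistry, GenotypeTable, build_registry


class GenepopParseError(ValueError):
    """Raised with the offending line number on malformed Genepop input."""


_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path) -> GenotypeTable:
    """Parse a Genepop (.gen) file into a :class:`GenotypeTable`.

    Samples are the POP blocks, labelled ``pop_1``, ``pop_2``, ... in
    file order; site mirrors the sample label and substrate is unknown
    (the format carries no such metadata).  Allele codes are preserved
    verbatim as labels; all-zero codes become missing genotypes.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    # locus names: lines 2.. until first POP; a single comma-separated line allowed
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError(f"no POP line found (file {path})")
    if not loci:
        raise GenepopParseError(f"no locus names before first POP (line {i + 1})")

    records = []
    pop_idx = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _POP_RE.match(line):
            pop_idx += 1
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenepopParseError(f"line {lineno + 1}: expected 'id , genotypes'")
        iid, _, rest = line.partition(",")
        iid = iid.strip()
        codes = rest.split()
        if len(codes) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: {len(codes)} genotype fields for {len(loci)} loci"
            )
        genos = []
        for code in codes:
            if len(code) not in (4, 6) or not code.isdigit():
                raise GenepopParseError(
                    f"line {lineno + 1}: bad allele string {code!r} "
                    "(need 4 or 6 digits)"
                )
            w = len(code) // 2
            a1, a2 = code[:w], code[w:]
            zero = "0" * w
            if a1 == zero or a2 == zero:
                genos.append(None)
            else:
                genos.append((a1, a2))
        sample = f"pop_{pop_idx}"
        records.append((iid, sample, sample, "unknown", genos))
    if not records:
        raise GenepopParseError("no individual records")
    return GenotypeTable.from_records(loci, records)


def write_genepop(table: GenotypeTable, path, title: str = "musselmix export",
                  digits: int = 3) -> None:
    """Write a :class:`GenotypeTable` as a Genepop file.

    Allele labels must be numeric strings no wider than *digits*.
    """
    zero = "0" * digits
    out = [title]
    out.extend(table.loci)
    miss = table.missing_mask()
    for s, sub in table.by_sample().items():
        out.append("POP")
        submiss = sub.missing_mask()
        for i, iid in enumerate(sub.ids):
            codes = []
            for j in range(len(table.loci)):
                if submiss[i, j]:
                    codes.append(zero + zero)
                else:
                    a1, a2 = sub.alleles[i, j]
                    for a in (a1, a2):
                        if not a.isdigit() or len(a) > digits:
                            raise ValueError(
                                f"allele label {a!r} not encodable with {digits} digits"
                            )
                    codes.append(a1.zfill(digits) + a2.zfill(digits))
            out.append(f"{iid} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


def read_tabular(path) -> GenotypeTable:
    """Read the tabular genotype dialect (TSV, one row per individual)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["id", "sample", "site", "substrate"]
    if df.columns[: len(fixed)].tolist() != fixed:
        raise ValueError(f"tabular file must start with columns {fixed}")
    loci = df.columns[len(fixed):].tolist()
    if not loci:
        raise ValueError("no locus columns")
    records = []
    for _, row in df.iterrows():
        genos = []
        for locus in loci:
            cell = row[locus]
            if pd.isna(cell) or cell in ("./.", ".", ""):
                genos.append(None)
            else:
                parts = cell.split("/")
                if len(parts) != 2:
                    raise ValueError(f"bad genotype cell {cell!r} for {row['id']}")
                genos.append((parts[0], parts[1]))
        sub = row["substrate"] if row["substrate"] in SUBSTRATES else "unknown"
        records.append((row["id"], row["sample"], row["site"], sub, genos))
    return GenotypeTable.from_records(loci, records)


def write_tabular(table: GenotypeTable, path) -> None:
    miss = table.missing_mask()
    rows = []
    for i, iid in enumerate(table.ids):
        meta = table.individuals.loc[iid]
        row = {"id": iid, "sample": meta["sample"], "site": meta["site"],
               "substrate": meta["substrate"]}
        for j, locus in enumerate(table.loci):
            row[locus] = "./." if miss[i, j] else "/".join(table.alleles[i, j])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_registry(path) -> AlleleRegistry:
    """Load an allele registry from a YAML config.

    Layout::

        loci:
          Est-D:
            alleles:
              "90":  {ME: 0.05, MT: 0.95}
              "100": {ME: 0.95, MT: 0.05}

    Pooling and compound reference frequencies are derived from the
    per-taxon allele frequencies via :func:`build_registry`.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    ref_me: dict[str, dict[str, float]] = {}
    ref_mt: dict[str, dict[str, float]] = {}
    for locus, entry in cfg["loci"].items():
        ref_me[locus] = {str(a): float(f["ME"]) for a, f in entry["alleles"].items()}
        ref_mt[locus] = {str(a): float(f["MT"]) for a, f in entry["alleles"].items()}
    return build_registry(ref_me, ref_mt)


def write_registry(ref_me: Mapping[str, Mapping[str, float]],
                   ref_mt: Mapping[str, Mapping[str, float]], path) -> None:
    cfg = {"loci": {}}
    for locus in ref_me:
        alleles = {}
        for a in set(ref_me[locus]) | set(ref_mt[locus]):
            alleles[str(a)] = {"ME": float(ref_me[locus].get(a, 0.0)),
                               "MT": float(ref_mt[locus].get(a, 0.0))}
        cfg["loci"][locus] = {"alleles": alleles}
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
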