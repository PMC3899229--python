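"""Readers and writers for Structure- and Genepop-format genotype files.

Both formats are plain text and ubiquitous in microsatellite studies; the
parsers here are deliberately strict (ragged rows and inconsistent allele
coding are errors, not warnings) because silent column drift is the classic
failure mode of these files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import MISSING, GenotypeMatrix, IndividualMeta, Locus


@dataclass
class StructureDialect:
    """Configuration of a Structure text file.

    two_rows: two lines per individual (one allele copy per line) when True,
        otherwise one line with 2L adjacent allele columns.
    missing_code: integer code standing for a missing allele copy.
    has_popflag: whether a popflag column (0/1) follows the pop column.
    """

    two_rows: bool = True
    missing_code: int = -9
    has_popflag: bool = False


def read_structure_file(path: str | Path,
                        dialect: StructureDialect | None = None
                        ) -> GenotypeMatrix:
    """Parse a Structure genotype file into a :class:`GenotypeMatrix`.

    The first line must hold the locus names; each data line is
    ``label pop [popflag] a_1 ... a_L`` (two-rows dialect) or
    ``label pop [popflag] a_1 b_1 ... a_L b_L`` (one-row dialect).
    """
    dialect = dialect or StructureDialect()
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    locus_names = lines[0].split()
    L = len(locus_names)
    meta_cols = 3 if dialect.has_popflag else 2
    per_line = L if dialect.two_rows else 2 * L

    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        toks = ln.split()
        if len(toks) != meta_cols + per_line:
            raise ValueError(
                f"{path}: line {lineno}: expected {meta_cols + per_line} "
                f"columns, found {len(toks)}"
            )
        try:
            allele_toks = [int(t) for t in toks[meta_cols:]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-integer allele code") from exc
        rows.append((lineno, toks[:meta_cols], allele_toks))

    records: list[tuple[IndividualMeta, list[int]]] = []
    if dialect.two_rows:
        if len(rows) % 2:
            raise ValueError(f"{path}: odd number of data rows in two-row dialect")
        for (ln_a, meta_a, row_a), (ln_b, meta_b, row_b) in zip(rows[::2], rows[1::2]):
            if meta_a != meta_b:
                raise ValueError(
                    f"{path}: lines {ln_a}/{ln_b}: the two rows of individual "
                    f"{meta_a[0]!r} disagree on label/pop columns"
                )
            copies = [c for pair in zip(row_a, row_b) for c in pair]
            records.append((_meta_from(meta_a, dialect), copies))
    else:
        for _, meta, row in rows:
            records.append((_meta_from(meta, dialect), row))

    calls = np.full((len(records), L, 2), MISSING, dtype=np.int64)
    for i, (_, copies) in enumerate(records):
        arr = np.array(copies, dtype=np.int64).reshape(L, 2)
        calls[i] = np.where(arr == dialect.missing_code, MISSING, arr)
    loci = _build_loci(locus_names, calls)
    return GenotypeMatrix([m for m, _ in records], loci, calls)


def _meta_from(meta_tokens: list[str], dialect: StructureDialect) -> IndividualMeta:
    label, pop = meta_tokens[0], meta_tokens[1]
    popflag = bool(int(meta_tokens[2])) if dialect.has_popflag else False
    return IndividualMeta(id=label, group=pop, popflag=popflag)


def _build_loci(names: list[str], calls: np.ndarray) -> list[Locus]:
    loci = []
    for j, name in enumerate(names):
        observed = calls[:, j, :]
        alleles = sorted(set(observed[observed != MISSING].tolist()))
        loci.append(Locus(name, tuple(alleles)))
    return loci


def write_structure_file(gm: GenotypeMatrix, path: str | Path,
                         dialect: StructureDialect | None = None) -> None:
    dialect = dialect or StructureDialect()
    out = [" ".join(gm.locus_names)]
    for i, ind in enumerate(gm.individuals):
        meta = [ind.id, ind.group]
        if dialect.has_popflag:
            meta.append("1" if ind.popflag else "0")
        coded = np.where(gm.calls[i] == MISSING, dialect.missing_code, gm.calls[i])
        if dialect.two_rows:
            for copy in (0, 1):
                out.append(" ".join(meta + [str(int(a)) for a in coded[:, copy]]))
        else:
            out.append(" ".join(meta + [str(int(a)) for a in coded.ravel()]))
    Path(path).write_text("\n".join(out) + "\n")


# -- Genepop -----------------------------------------------------------------


def read_genepop_file(path: str | Path,
                      group_names: list[str] | None = None) -> GenotypeMatrix:
    """Parse a Genepop file (2- or 3-digit allele coding, ``Pop`` separators).

    Groups are named after the first individual label of each Pop block
    unless ``group_names`` supplies explicit names. ``00``/``000`` codes a
    missing allele copy. Mixing 2- and 3-digit coding within a locus is an
    error.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: truncated Genepop file")
    # line 0 is a free-text title
    body = lines[1:]
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        locus_names.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    if not locus_names:
        raise ValueError(f"{path}: no locus names before first Pop line")
    L = len(locus_names)

    blocks: list[list[tuple[str, list[str]]]] = []
    for ln in body[i:]:
        if not ln.strip():
            continue
        if ln.strip().lower() == "pop":
            blocks.append([])
            continue
        if "," not in ln:
            raise ValueError(f"{path}: malformed individual line {ln!r}")
        label, geno = ln.split(",", 1)
        toks = geno.split()
        if len(toks) != L:
            raise ValueError(
                f"{path}: individual {label.strip()!r}: {len(toks)} genotype "
                f"fields for {L} loci"
            )
        blocks[-1].append((label.strip(), toks))

    # per-locus digit width must be consistent
    widths = [set() for _ in range(L)]
    for block in blocks:
        for _, toks in block:
            for j, t in enumerate(toks):
                if len(t) not in (4, 6):
                    raise ValueError(f"{path}: genotype field {t!r} has bad width")
                widths[j].add(len(t) // 2)
    for j, w in enumerate(widths):
        if len(w) > 1:
            raise ValueError(
                f"{path}: locus {locus_names[j]}: mixed 2- and 3-digit coding"
            )

    individuals: list[IndividualMeta] = []
    calls_rows: list[np.ndarray] = []
    for b, block in enumerate(blocks):
        if not block:
            continue
        gname = (group_names[b] if group_names and b < len(group_names)
                 else block[0][0])
        for label, toks in block:
            row = np.full((L, 2), MISSING, dtype=np.int64)
            for j, t in enumerate(toks):
                w = len(t) // 2
                a, bb = int(t[:w]), int(t[w:])
                row[j, 0] = MISSING if a == 0 else a
                row[j, 1] = MISSING if bb == 0 else bb
            individuals.append(IndividualMeta(id=label, group=gname))
            calls_rows.append(row)
    calls = np.stack(calls_rows) if calls_rows else np.zeros((0, L, 2), dtype=np.int64)
    return GenotypeMatrix(individuals, _build_loci(locus_names, calls), calls)


def write_genepop_file(gm: GenotypeMatrix, path: str | Path,
                       digits: int = 3, title: str = "hybridkit export") -> None:
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    maxallele = int(gm.calls.max(initial=0))
    if maxallele >= 10 ** digits:
        raise ValueError(f"allele label {maxallele} does not fit {digits}-digit coding")
    out = [title]
    out.extend(gm.locus_names)
    for g in gm.groups:
        out.append("Pop")
        mask = gm.group_mask(g)
        for i in np.flatnonzero(mask):
            row = gm.calls[i]
            fields = []
            for j in range(gm.n_loci):
                a, b = row[j]
                a = 0 if a == MISSING else int(a)
                b = 0 if b == MISSING else int(b)
                fields.append(f"{a:0{digits}d}{b:0{digits}d}")
            out.append(f"{gm.individuals[i].id} , " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")
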