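"""Genepop text-format reading and writing.

Dialect: title line, one locus name per line (or comma-separated on one
line), then one or more ``POP`` blocks of ``id , 001002 003003 ...`` lines.
Allele codes are 2- or 3-digit (auto-detected on read, 3-digit written by
default); ``00``/``000`` denotes a missing allele and a call with any missing
allele is treated as fully missing.
"""
from __future__ import annotations

from .genotypes import MISSING, GenotypeMatrix


class GenepopParseError(ValueError):
    """Malformed Genepop input; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _is_pop_line(line: str) -> bool:
    return line.strip().lower() == "pop"


def read_genepop(path) -> GenotypeMatrix:
    """Read a Genepop file into a :class:`GenotypeMatrix`.

    Population blocks are concatenated; block membership is retained in
    ``populations`` as ``pop1``, ``pop2``, ...
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenepopParseError("empty file", 1)

    # locus names: lines 2.. until the first POP
    locus_names: list[str] = []
    i = 1
    while i < len(raw) and not _is_pop_line(raw[i]):
        line = raw[i].strip()
        if line:
            if "," in line:
                locus_names.extend(t.strip() for t in line.split(",") if t.strip())
            else:
                locus_names.append(line)
        i += 1
    if i >= len(raw):
        raise GenepopParseError("no POP line found", len(raw))
    if not locus_names:
        raise GenepopParseError("no locus names before first POP", i + 1)

    ids: list[str] = []
    pops: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_no = 0
    while i < len(raw):
        if _is_pop_line(raw[i]):
            pop_no += 1
            i += 1
            continue
        line = raw[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise GenepopParseError("expected 'id , genotypes' line", i + 1)
        ind_id, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise GenepopParseError(
                f"expected {len(locus_names)} genotypes, got {len(tokens)}", i + 1)
        row = []
        for tok in tokens:
            if not tok.isdigit():
                raise GenepopParseError(f"non-numeric genotype {tok!r}", i + 1)
            if len(tok) == 4:
                w = 2
            elif len(tok) == 6:
                w = 3
            else:
                raise GenepopParseError(
                    f"genotype {tok!r} is neither 4 nor 6 digits", i + 1)
            if width is None:
                width = w
            elif w != width:
                raise GenepopParseError(
                    f"inconsistent allele-code width in {tok!r}", i + 1)
            a1, a2 = int(tok[:w]), int(tok[w:])
            if a1 == 0 or a2 == 0:
                a1 = a2 = MISSING
            row.append((a1, a2))
        ids.append(ind_id.strip())
        pops.append(f"pop{pop_no}")
        calls.append(row)
        i += 1

    if not calls:
        raise GenepopParseError("file contains no individuals", len(raw))
    return GenotypeMatrix(calls, locus_names, ids, pops)


def write_genepop(gm: GenotypeMatrix, path, title: str = "ldpopsize export",
                  width: int = 3) -> None:
    """Write a :class:`GenotypeMatrix` as a Genepop file.

    Output is deterministic for a fixed input.  Raises if any allele code
    does not fit the chosen digit width or if the matrix is empty.
    """
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    if width not in (2, 3):
        raise ValueError("width must be 2 or 3")
    limit = 10 ** width
    if int(gm.calls.max(initial=0)) >= limit:
        raise ValueError(f"allele code >= {limit} cannot be written at width {width}")

    pops = gm.populations or ["pop1"] * gm.n_individuals
    lines = [title]
    lines.extend(gm.locus_names)
    current = None
    for ind, pop, row in zip(gm.individual_ids, pops, gm.calls):
        if pop != current:
            lines.append("POP")
            current = pop
        geno = " ".join(f"{a1:0{width}d}{a2:0{width}d}" for a1, a2 in row)
        lines.append(f"{ind} ,  {geno}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
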