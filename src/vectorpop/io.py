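"""File I/O: GENEPOP genotype files, labeled matrices, YAML configs.

GENEPOP conventions followed: first line is a free title; locus names come
one per line (or comma-separated on one line); each "Pop" keyword starts a
new population block; individual lines are ``<id> ,  <code> <code> ...``
where each code concatenates two fixed-width (2- or 3-digit) allele sizes
and "00"/"000" marks a missing allele. The site label of an individual is
the last whitespace-separated token of its identifier.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .panel import MISSING, GenotypePanel


class GenepopParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def read_genepop(path: str | Path) -> GenotypePanel:
    """Parse a GENEPOP file into a :class:`GenotypePanel`."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file", 1)
    # locus names: everything between the title and the first Pop line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend([t.strip() for t in chunk.split(",") if t.strip()])
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'Pop' keyword found", len(lines))
    if not loci:
        raise GenepopParseError("no locus names before first 'Pop'", i + 1)

    individuals, sites, rows = [], [], []
    pop_start_line = None
    n_in_pop = 0
    while i < len(lines):
        line = lines[i]
        stripped = line.strip()
        if stripped.lower() == "pop":
            if pop_start_line is not None and n_in_pop == 0:
                raise GenepopParseError("empty Pop block", pop_start_line + 1)
            pop_start_line = i
            n_in_pop = 0
            i += 1
            continue
        if not stripped:
            i += 1
            continue
        if "," not in stripped:
            raise GenepopParseError("individual line lacks ','", i + 1)
        ident, geno_part = stripped.split(",", 1)
        ident = ident.strip()
        site = ident.split()[-1] if ident else f"pop{pop_start_line}"
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise GenepopParseError(
                f"expected {len(loci)} genotypes, found {len(codes)}", i + 1
            )
        pair_row = []
        for code in codes:
            if len(code) % 2 != 0 or len(code) not in (4, 6):
                raise GenepopParseError(
                    f"genotype code {code!r} is not 2x2 or 2x3 digits", i + 1
                )
            half = len(code) // 2
            a1, a2 = int(code[:half]), int(code[half:])
            if a1 == 0 or a2 == 0:
                a1 = a2 = MISSING
            pair_row.append((a1, a2))
        individuals.append(ident)
        sites.append(site)
        rows.append(pair_row)
        n_in_pop += 1
        i += 1
    if pop_start_line is not None and n_in_pop == 0:
        raise GenepopParseError("empty Pop block", pop_start_line + 1)
    genotypes = np.array(rows, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    return GenotypePanel(individuals, np.array(sites, dtype=object), loci, genotypes)


def write_genepop(panel: GenotypePanel, path: str | Path,
                  title: str = "vectorpop synthetic panel") -> None:
    """Write a panel as GENEPOP with 3-digit allele codes, one Pop per site."""
    if (panel.genotypes > 999).any():
        raise ValueError("allele size exceeds 3-digit GENEPOP code")
    out = [title]
    out.extend(panel.loci)
    for site, rows in panel.group_indices(by="site").items():
        out.append("Pop")
        for r in rows:
            codes = []
            for j in range(panel.n_loci):
                a1, a2 = panel.genotypes[r, j]
                codes.append(f"{a1:03d}{a2:03d}")
            ident = panel.individuals[r]
            # keep the site recoverable as the id's last token
            if ident.split()[-1] != site:
                ident = f"{ident} {site}"
            out.append(f"{ident} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------
def read_config(path: str | Path) -> dict:
    """Load a structured key-value (YAML) pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
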