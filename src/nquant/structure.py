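"""Per-residue B-factor profiling and haplotype annotation of ANKK1 models.

ANKK1 (UniProt Q8NFD2, 765 residues) carries an N-terminal RIP-kinase
domain (residues 22–289) and C-terminal ankyrin repeats (361–753).  The
AlphaFold model of the protein stores one value per residue in the
B-factor column; this module extracts that profile, summarises it globally
or per domain, and annotates the five polymorphic positions (239, 318,
442, 490, 713) that define the H2B/H2/H1 haplotypes with side-chain charge
classes.  Note that AlphaFold deposits its per-residue confidence (pLDDT)
in the B-factor field; values are reported verbatim as "B-factor (Å²)"
with the alternative "per-residue model confidence" reading flagged in
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResidueRecord",
    "DomainDef",
    "HaplotypeTable",
    "KINASE_DOMAIN",
    "ANKYRIN_DOMAIN",
    "CHARGE_CLASS",
    "charge_class",
    "parse_structure",
    "bfactor_summary",
    "annotate_haplotypes",
    "default_ankk1_haplotypes",
    "write_synthetic_alphafold_like_model",
]


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a structural model."""

    position: int        # 1-based sequence position
    aa: str              # one-letter amino acid code
    b_factor: float      # value of the B-factor column, Å²


@dataclass(frozen=True)
class DomainDef:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("domain start must be <= end")


KINASE_DOMAIN = DomainDef("kinase", 22, 289)
ANKYRIN_DOMAIN = DomainDef("ankyrin", 361, 753)

# side-chain charge at neutral pH; His counted positive, following the
# assay convention used for these haplotype comparisons
CHARGE_CLASS = {aa: "n" for aa in "ACDEFGHIKLMNPQRSTVWY"}
CHARGE_CLASS.update({"R": "+", "K": "+", "H": "+", "D": "-", "E": "-"})


def charge_class(aa: str) -> str:
    """Charge class of a one-letter amino acid: '+', '-' or 'n'."""
    try:
        return CHARGE_CLASS[aa.upper()]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


@dataclass(frozen=True)
class HaplotypeTable:
    """Amino acids carried by each haplotype at the variant positions.

    ``alleles`` maps position -> {haplotype -> one-letter aa}.  The H1
    haplotype carries Lys713, the change tagged by the TaqIA A1 allele.
    """

    alleles: dict

    @property
    def positions(self) -> list[int]:
        return sorted(self.alleles)

    @property
    def haplotypes(self) -> list[str]:
        first = self.alleles[self.positions[0]]
        return list(first)


def default_ankk1_haplotypes(h2b_239: str = "A") -> HaplotypeTable:
    """The ANKK1 H2B/H2/H1 table at positions 239, 318, 442, 490, 713.

    H2B's residue at 239 is configurable (default Ala, as in H2): only the
    H1-vs-H2 contrast at 239 (Thr vs Ala) is established.
    """
    return HaplotypeTable(alleles={
        239: {"H2B": h2b_239, "H2": "A", "H1": "T"},
        318: {"H2B": "G", "H2": "R", "H1": "G"},
        442: {"H2B": "G", "H2": "R", "H1": "R"},
        490: {"H2B": "H", "H2": "R", "H1": "H"},
        713: {"H2B": "E", "H2": "E", "H1": "K"},
    })


def parse_structure(structure_file: str | Path) -> list[ResidueRecord]:
    """Read a PDB/mmCIF model into per-residue records.

    One record per polymer residue of the first chain of the first model;
    the B-factor is taken from the Cα atom (AlphaFold writes the same
    value on every atom of a residue).  Raises on unreadable files or
    chains without Cα atoms.
    """
    import gemmi

    path = Path(structure_file)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"cannot read structure file {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError("structure has no models")
    model = st[0]
    if len(model) == 0:
        raise ValueError("model has no chains")
    chain = model[0]

    records: list[ResidueRecord] = []
    for res in chain:
        ca = res.find_atom("CA", "*")
        if ca is None:
            continue
        info = gemmi.find_tabulated_residue(res.name)
        one = info.one_letter_code.upper() if info else "X"
        pos = res.seqid.num
        records.append(ResidueRecord(position=pos, aa=one,
                                     b_factor=float(ca.b_iso)))
    if not records:
        raise ValueError("no Cα atoms found in the first chain")
    records.sort(key=lambda r: r.position)
    positions = [r.position for r in records]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate residue positions")
    return records


def bfactor_summary(records: list[ResidueRecord],
                    domain: DomainDef | None = None) -> dict:
    """Min/max/mean of the B-factor column, whole chain or one domain."""
    if not records:
        raise ValueError("no residues")
    if domain is not None:
        sel = [r for r in records if domain.start <= r.position <= domain.end]
        if not sel:
            raise ValueError(f"domain {domain.name} selects no residues")
    else:
        sel = records
    vals = np.array([r.b_factor for r in sel])
    return {"n": len(sel), "min": float(vals.min()),
            "max": float(vals.max()), "mean": float(vals.mean()),
            "domain": domain.name if domain else "all"}


def annotate_haplotypes(records: list[ResidueRecord],
                        table: HaplotypeTable) -> pd.DataFrame:
    """Per-variant-position report of alleles, charges and differing pairs.

    One row per position in ``table`` with each haplotype's amino acid and
    charge class, plus a boolean per haplotype pair marking whether the
    two differ there.  Positions outside the model's sequence raise.
    """
    by_pos = {r.position: r for r in records}
    haps = table.haplotypes
    rows = []
    for pos in table.positions:
        if pos not in by_pos:
            raise ValueError(f"variant position {pos} outside the model")
        alleles = table.alleles[pos]
        row: dict = {"position": pos, "model_aa": by_pos[pos].aa,
                     "b_factor": by_pos[pos].b_factor}
        for h in haps:
            row[f"{h}_aa"] = alleles[h]
            row[f"{h}_charge"] = charge_class(alleles[h])
        for i, a in enumerate(haps):
            for b in haps[i + 1:]:
                row[f"differs_{a}_{b}"] = alleles[a] != alleles[b]
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")


# ---------------------------------------------------------------------------
# synthetic fixture support

_THREE = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
          "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
          "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
          "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}


def write_synthetic_alphafold_like_model(path: str | Path,
                                         n_residues: int = 765,
                                         seed: int = 0) -> Path:
    """Write a SYNTHETIC Cα-only PDB stand-in for an AlphaFold-style model.

    This is a generated fixture, not the real AlphaFold entry: residues
    are random, coordinates follow a loose helix, and the B-factor column
    carries a smooth synthetic profile in the pLDDT-like range 25–99.  It
    exercises parsing/summary code paths only; its numbers have no
    biological meaning.
    """
    rng = np.random.default_rng(seed)
    aas = rng.choice(list(_THREE), size=n_residues)
    # smooth bounded profile: random walk squashed into [25, 99]
    walk = np.cumsum(rng.normal(0, 1.0, n_residues))
    prof = 62.0 + 37.0 * np.tanh(walk / max(1.0, walk.std() * 1.5))
    lines = []
    for i in range(n_residues):
        t = i * 0.6
        x, y, z = 2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {_THREE[aas[i]]} A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{prof[i]:6.2f}           C")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
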