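"""Physico-chemical descriptors at pH 7.4 and compound-table I/O.

A compound is profiled by ten descriptors: six continuous (molar mass,
percentage of aromatic atoms, polar surface area, log D at pH 7.4, log S,
log P) and four discrete counts (rotatable bonds, H-bond acceptors and
donors at pH 7.4, net formal charge at pH 7.4).

Two providers produce a :class:`DescriptorSet`:

* the **table backend** (:func:`load_descriptor_table`) reads precomputed
  descriptor columns and is the authoritative route for reproducing
  published numbers;
* the **computed backend** (:func:`compute_descriptors`) derives a
  best-effort profile from a SMILES structure with RDKit, using a
  rule-based ionisation model for the pH-dependent fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DescriptorUnavailableError,
    DuplicateIdError,
    IncompleteDescriptorsError,
    StructureParseError,
    TableFormatError,
)

#: Continuous descriptors, in canonical column order.
CONTINUOUS_DESCRIPTORS: tuple[str, ...] = (
    "molar_mass",
    "aromatic_pct",
    "psa",
    "logd74",
    "logs",
    "logp",
)

#: Discrete (integer-valued) descriptors, in canonical column order.
DISCRETE_DESCRIPTORS: tuple[str, ...] = (
    "rotatable_bonds",
    "hba74",
    "hbd74",
    "formal_charge74",
)

#: All ten descriptors in canonical column order.
ALL_DESCRIPTORS: tuple[str, ...] = CONTINUOUS_DESCRIPTORS + DISCRETE_DESCRIPTORS

#: Canonical CSV header for descriptor tables.
CANONICAL_COLUMNS: tuple[str, ...] = ("compound_id", "smiles", *ALL_DESCRIPTORS, "group")


@dataclass(frozen=True)
class DescriptorSet:
    """The ten physico-chemical descriptors of one compound.

    Units: ``molar_mass`` in g/mol, ``psa`` in Å², ``aromatic_pct`` in
    percent of heavy atoms; the log coefficients are unitless; the four
    count fields are integers (formal charge may be negative).
    """

    molar_mass: float
    aromatic_pct: float
    psa: float
    logd74: float
    logs: float
    logp: float
    rotatable_bonds: int
    hba74: int
    hbd74: int
    formal_charge74: int

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")
        if not 0.0 <= self.aromatic_pct <= 100.0:
            raise ValueError(f"aromatic_pct must be in [0, 100], got {self.aromatic_pct}")
        if self.psa < 0:
            raise ValueError(f"psa must be non-negative, got {self.psa}")
        for name in ("rotatable_bonds", "hba74", "hbd74"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if not isinstance(self.formal_charge74, int):
            raise ValueError(
                f"formal_charge74 must be an integer, got {self.formal_charge74!r}"
            )
        for name in CONTINUOUS_DESCRIPTORS:
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"{name} must be finite, got {v!r}")

    def as_dict(self) -> dict[str, float | int]:
        return {name: getattr(self, name) for name in ALL_DESCRIPTORS}


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identifier plus structure and/or descriptors."""

    compound_id: str
    smiles: str | None = None
    descriptors: DescriptorSet | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.smiles is None and self.descriptors is None:
            raise ValueError(
                f"compound {self.compound_id!r}: at least one of smiles, "
                "descriptors must be present"
            )

    def with_descriptors(self, descriptors: DescriptorSet) -> "CompoundRecord":
        return replace(self, descriptors=descriptors)


@dataclass(frozen=True)
class RejectedRow:
    """A table row or compound that failed validation, with the reason."""

    compound_id: str
    reason: str


# --------------------------------------------------------------------------
# Computed backend (RDKit + rule-based ionisation)
# --------------------------------------------------------------------------

#: Ionisable-group rules: (label, SMARTS, kind, literature pKa).
#: ``kind`` is "acid" (deprotonates when pH > pKa) or "base" (the conjugate
#: acid deprotonates when pH > pKa, i.e. the base is protonated below pKa).
#: pKa values are representative group constants, not per-molecule
#: predictions; see the methods note.
IONISABLE_GROUPS: tuple[tuple[str, str, str, float], ...] = (
    ("sulfonic_acid", "[SX4](=O)(=O)[OX2H1]", "acid", -1.0),
    ("phosphonic_acid", "[PX4](=O)([OX2H1])", "acid", 2.0),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]", "acid", 4.5),
    ("tetrazole", "c1nnn[nH]1", "acid", 4.9),
    ("phenol", "[c][OX2H1]", "acid", 10.0),
    ("thiol", "[#6][SX2H1]", "acid", 10.5),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]", "base", 13.0),
    ("amidine", "[CX3;!$(C(N)(N)=N)](=[NX2;!$(N=C-N)])[NX3]", "base", 11.5),
    (
        "aliphatic_amine",
        "[NX3;H2,H1,H0;+0;!$(N-[a]);!$(N-[#6]=[O,S,N]);!$(N-[S,P]=O);!$(N~[!#6;!#1])]",
        "base",
        10.5,
    ),
    ("pyridine_n", "[nX2;+0;!$([n][#8])]", "base", 5.2),
    ("aniline", "[NX3;H2,H1;+0;$(N-[a]);!$(N-[#6]=[O,S,N])]", "base", 4.6),
)

_PH = 7.4


@dataclass(frozen=True)
class ProviderConfig:
    """Options of the computed backend.

    ionization: "rules" applies the built-in group-pKa model at pH 7.4;
        "none" disables it, in which case any molecule carrying a
        recognised ionisable group raises :class:`DescriptorUnavailableError`
        rather than returning neutral-species values for pH-dependent
        fields.
    aromatic_include_h: include hydrogens in the aromatic-percentage
        denominator (default counts heavy atoms only).
    keep_largest_fragment: strip salts/solvents by keeping the largest
        covalent component.
    """

    ionization: str = "rules"
    aromatic_include_h: bool = False
    keep_largest_fragment: bool = True

    def __post_init__(self) -> None:
        if self.ionization not in ("rules", "none"):
            raise ValueError(f"unknown ionization model: {self.ionization!r}")


def _find_ionisable_sites(mol) -> list[tuple[str, str, float, int]]:
    """Return (label, kind, pKa, atom_idx) for each ionisable site.

    Each atom is claimed by at most one rule; rules are tried in the
    declared (strongest-first within class) order.
    """
    from rdkit import Chem

    sites: list[tuple[str, str, float, int]] = []
    claimed: set[int] = set()
    for label, smarts, kind, pka in IONISABLE_GROUPS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            # the protonatable/deprotonatable atom is the last O/N/S atom
            # of the match for acids, the first N for bases
            if kind == "acid":
                atom_idx = next(
                    i for i in reversed(match)
                    if mol.GetAtomWithIdx(i).GetSymbol() in ("O", "S", "N")
                )
            else:
                atom_idx = next(
                    i for i in match if mol.GetAtomWithIdx(i).GetSymbol() == "N"
                )
            if atom_idx in claimed:
                continue
            claimed.add(atom_idx)
            sites.append((label, kind, pka, atom_idx))
    return sites


def compute_descriptors(
    smiles: str, provider_config: ProviderConfig | None = None
) -> DescriptorSet:
    """Compute the ten descriptors from a SMILES string.

    Deterministic for a fixed ``provider_config``. Multi-fragment input
    (salts) is reduced to its largest covalent component first. The
    pH-dependent fields (log D, HBA/HBD, formal charge at pH 7.4) are
    evaluated on the major protonation state assigned by the group-pKa
    rules; log S uses the ESOL regression of Delaney (2004).

    Raises
    ------
    StructureParseError
        if the SMILES does not parse.
    DescriptorUnavailableError
        if the ionisation model is disabled but required.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    cfg = provider_config or ProviderConfig()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)

    if cfg.keep_largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())

    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        raise StructureParseError(smiles, "no heavy atoms")
    n_aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    if cfg.aromatic_include_h:
        total = sum(a.GetTotalNumHs() + 1 for a in mol.GetAtoms())
    else:
        total = heavy
    aromatic_pct = 100.0 * n_aromatic / total

    logp = Crippen.MolLogP(mol)
    molar_mass = Descriptors.MolWt(mol)
    psa = Descriptors.TPSA(mol)
    rotatable = int(Lipinski.NumRotatableBonds(mol))

    # ESOL estimate (Delaney 2004): intercept 0.16, clogP, MW, rotatable
    # bonds, aromatic proportion (fraction of heavy atoms)
    logs = (
        0.16
        - 0.63 * logp
        - 0.0062 * molar_mass
        + 0.066 * rotatable
        - 0.74 * (n_aromatic / heavy)
    )

    sites = _find_ionisable_sites(mol)
    if cfg.ionization == "none" and sites:
        labels = sorted({s[0] for s in sites})
        raise DescriptorUnavailableError(
            f"{smiles!r} carries ionisable groups ({', '.join(labels)}) but the "
            "ionisation model is disabled; pH 7.4 descriptors are unavailable"
        )

    # Build the major protonation state at pH 7.4: deprotonate acids with
    # pKa < pH, protonate bases with conjugate-acid pKa > pH.
    charged = Chem.RWMol(mol)
    hh_deficit = 0.0  # -log10 of the neutral-species fraction, summed per site
    for _label, kind, pka, atom_idx in sites:
        atom = charged.GetAtomWithIdx(atom_idx)
        if kind == "acid":
            hh_deficit += math.log10(1.0 + 10.0 ** (_PH - pka))
            if pka < _PH:
                atom.SetFormalCharge(atom.GetFormalCharge() - 1)
                atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
                atom.SetNoImplicit(True)
        else:
            hh_deficit += math.log10(1.0 + 10.0 ** (pka - _PH))
            if pka > _PH:
                atom.SetFormalCharge(atom.GetFormalCharge() + 1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
    major = charged.GetMol()
    Chem.SanitizeMol(major)

    # Henderson–Hasselbalch correction: log D = log P + log10(f_neutral),
    # treating sites as independent. Zero when nothing ionises.
    logd74 = logp - hh_deficit

    return DescriptorSet(
        molar_mass=molar_mass,
        aromatic_pct=aromatic_pct,
        psa=psa,
        logd74=logd74,
        logs=logs,
        logp=logp,
        rotatable_bonds=rotatable,
        hba74=int(Lipinski.NumHAcceptors(major)),
        hbd74=int(Lipinski.NumHDonors(major)),
        formal_charge74=int(Chem.GetFormalCharge(major)),
    )


# --------------------------------------------------------------------------
# Table backend
# --------------------------------------------------------------------------


def _parse_float(cell: str) -> float:
    # locale-independent: decimal point only
    return float(cell.strip())


def load_descriptor_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[CompoundRecord], list[RejectedRow]]:
    """Read a CSV/TSV compound table into records plus a rejects list.

    ``column_map`` maps canonical names (``compound_id``, ``smiles``,
    descriptor names, ``group``) to the file's column headers; canonical
    headers need no mapping. Descriptor columns that are entirely absent
    leave ``descriptors`` unset (structure-only tables); rows with a
    missing value in a present descriptor column are rejected with a
    reason. Count columns accept integral floats ("1.0") but reject
    fractional values.

    Raises
    ------
    TableFormatError
        missing ``compound_id`` column, or a non-empty cell that does not
        parse as a number (reported with row/column coordinates).
    DuplicateIdError
        repeated compound identifiers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    colmap = dict(column_map or {})
    def col(name: str) -> str | None:
        actual = colmap.get(name, name)
        return actual if actual in df.columns else None

    id_col = col("compound_id")
    if id_col is None:
        raise TableFormatError(f"{path}: no compound_id column (have {list(df.columns)})")
    smiles_col = col("smiles")
    group_col = col("group")
    desc_cols = {name: col(name) for name in ALL_DESCRIPTORS}
    present = {name: c for name, c in desc_cols.items() if c is not None}

    ids = [v.strip() for v in df[id_col]]
    seen: set[str] = set()
    dups = {i for i in ids if i in seen or seen.add(i)}  # type: ignore[func-returns-value]
    if dups:
        raise DuplicateIdError(dups)

    records: list[CompoundRecord] = []
    rejects: list[RejectedRow] = []
    for row_idx, row in df.iterrows():
        cid = str(row[id_col]).strip()
        smiles = None
        if smiles_col is not None:
            s = str(row[smiles_col]).strip()
            smiles = s or None
        group = None
        if group_col is not None:
            g = str(row[group_col]).strip()
            group = g or None

        descriptors = None
        if present:
            values: dict[str, float | int] = {}
            missing: list[str] = []
            bad_reason: str | None = None
            for name, c in present.items():
                cell = str(row[c]).strip()
                if cell == "" or cell.lower() in ("na", "nan", "none"):
                    missing.append(name)
                    continue
                try:
                    v = _parse_float(cell)
                except ValueError:
                    raise TableFormatError(
                        f"{path}: non-numeric value {cell!r} at row {row_idx + 2}, "
                        f"column {c!r}"
                    ) from None
                if name in DISCRETE_DESCRIPTORS:
                    if v != int(v):
                        bad_reason = f"non-integer count in {name!r}: {cell}"
                        break
                    values[name] = int(v)
                else:
                    values[name] = v
            if bad_reason is not None:
                rejects.append(RejectedRow(cid, bad_reason))
                continue
            if missing:
                if len(missing) == len(ALL_DESCRIPTORS) and smiles is not None:
                    descriptors = None  # structure-only row in a mixed table
                else:
                    rejects.append(
                        RejectedRow(cid, f"missing descriptors: {', '.join(sorted(missing))}")
                    )
                    continue
            else:
                if len(values) < len(ALL_DESCRIPTORS):
                    absent = sorted(set(ALL_DESCRIPTORS) - set(values))
                    rejects.append(
                        RejectedRow(cid, f"table lacks columns for: {', '.join(absent)}")
                    )
                    continue
                try:
                    descriptors = DescriptorSet(**values)  # type: ignore[arg-type]
                except ValueError as exc:
                    rejects.append(RejectedRow(cid, str(exc)))
                    continue

        if smiles is None and descriptors is None:
            rejects.append(RejectedRow(cid, "neither smiles nor descriptors present"))
            continue
        records.append(CompoundRecord(cid, smiles=smiles, descriptors=descriptors, group=group))
    return records, rejects


def write_descriptor_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records as the canonical descriptor CSV.

    Continuous descriptors are formatted with two decimals, counts as
    integers; absent fields are left empty.
    """
    rows = []
    for rec in records:
        row: dict[str, str] = {"compound_id": rec.compound_id}
        row["smiles"] = rec.smiles or ""
        if rec.descriptors is not None:
            d = rec.descriptors
            for name in CONTINUOUS_DESCRIPTORS:
                row[name] = f"{getattr(d, name):.2f}"
            for name in DISCRETE_DESCRIPTORS:
                row[name] = str(getattr(d, name))
        else:
            for name in ALL_DESCRIPTORS:
                row[name] = ""
        row["group"] = rec.group or ""
        rows.append(row)
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, index=False)


def read_smiles_file(path: str | Path) -> list[CompoundRecord]:
    """Read a SMILES line file: one structure per line, optional id after whitespace."""
    records: list[CompoundRecord] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"line{i}"
        records.append(CompoundRecord(cid, smiles=smiles))
    return records


def read_sdf_file(path: str | Path) -> list[CompoundRecord]:
    """Read an SDF (v2000/v3000); ids from the molecule name, else SDF index."""
    from rdkit import Chem

    records: list[CompoundRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            raise StructureParseError(f"<SDF entry {i} in {path}>")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
        records.append(CompoundRecord(cid, smiles=Chem.MolToSmiles(mol)))
    return records


def require_complete(records: Sequence[CompoundRecord]) -> None:
    """Raise IncompleteDescriptorsError for the first record lacking descriptors."""
    for rec in records:
        if rec.descriptors is None:
            raise IncompleteDescriptorsError(rec.compound_id, ALL_DESCRIPTORS)


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Descriptor DataFrame (one row per record, canonical column order).

    All records must carry complete descriptors.
    """
    require_complete(records)
    data = {"compound_id": [r.compound_id for r in records]}
    for name in ALL_DESCRIPTORS:
        data[name] = [getattr(r.descriptors, name) for r in records]
    return pd.DataFrame(data).set_index("compound_id")
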