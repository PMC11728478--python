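"""Molecular structure handling and tabular input/output.

Molecules are parsed from SMILES with RDKit and represented by a hashed
path-based substructure fingerprint (paths up to 7 bonds folded to 1024 bits
by default) — a fixed-width binary encoding of structure characteristics that
the applicability-domain rules and the multitask forest both operate on.

Tabular formats (one row per ingredient / per formulation):

* formulation CSV: ``formulation_id, ingredient_name, smiles, concentration_pct``
* assay CSV: ``formulation_id, dpra_cys_depletion_pct, dpra_lys_depletion_pct,
  dpra_lys_coelution, hclat_mit_ug_ml, ghs_label`` (plus an optional
  ``insilico_call`` column carrying a precomputed positive/negative/missing
  in silico verdict for the formulation)
* plain SMILES lists, one molecule per line, for single-chemical mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import MoleculeParseError, SchemaError, TableRowError, ValidationError
from .itscore import DpraResult, HclatResult, ItsResult

RDLogger.DisableLog("rdApp.error")

DEFAULT_FP_BITS = 1024
DEFAULT_MAX_PATH = 7  # longest bond path hashed into the fingerprint

GHS_LABELS = ("NC", "1B", "1A")

FORMULATION_COLUMNS = ["formulation_id", "ingredient_name", "smiles", "concentration_pct"]
ASSAY_COLUMNS = [
    "formulation_id",
    "dpra_cys_depletion_pct",
    "dpra_lys_depletion_pct",
    "dpra_lys_coelution",
    "hclat_mit_ug_ml",
]


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule: input and canonical SMILES plus its fingerprint."""

    smiles: str
    canonical_smiles: str
    fingerprint: np.ndarray  # uint8 bit vector
    heavy_atom_count: int

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Molecule)
            and self.canonical_smiles == other.canonical_smiles
            and np.array_equal(self.fingerprint, other.fingerprint)
        )

    def __hash__(self) -> int:
        return hash(self.canonical_smiles)


@dataclass(frozen=True)
class Ingredient:
    """One formulation component.

    ``molecule`` is ``None`` for undefined structures (empty SMILES cells,
    inorganics the parser rejects, UVCBs); such ingredients propagate a
    "cannot be predicted" in silico verdict instead of failing.
    Concentration is percent w/w (0.1 means 0.1 %).
    """

    name: str
    molecule: Optional[Molecule]
    concentration: float

    def __post_init__(self):
        if self.concentration < 0:
            raise ValidationError(
                f"ingredient {self.name!r}: concentration {self.concentration} < 0"
            )


@dataclass
class Formulation:
    """An identified mixture of ingredients, optionally with a GHS truth label."""

    id: str
    ingredients: list[Ingredient]
    ghs_label: Optional[str] = None

    def __post_init__(self):
        if not self.ingredients:
            raise ValidationError(f"formulation {self.id!r} has no ingredients")
        if self.ghs_label is not None and self.ghs_label not in GHS_LABELS:
            raise ValidationError(
                f"formulation {self.id!r}: GHS label {self.ghs_label!r} not in {GHS_LABELS}"
            )
        total = sum(i.concentration for i in self.ingredients)
        if total > 100.0 + 1e-9:
            # other, unlisted ingredients are allowed, so > 100 is suspicious
            # but not fatal
            warnings.warn(
                f"formulation {self.id!r}: listed concentrations sum to {total:.2f}% > 100%",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AssayPanel:
    """DPRA and h-CLAT measurements (and optional extras) for one substance."""

    formulation_id: str
    dpra: Optional[DpraResult]
    hclat: Optional[HclatResult]
    ghs_label: Optional[str] = None
    insilico_call: Optional[str] = None  # "positive" | "negative" | "missing"


def compute_fingerprint(
    mol: Chem.Mol, n_bits: int = DEFAULT_FP_BITS, max_path: int = DEFAULT_MAX_PATH
) -> np.ndarray:
    """Hashed path-based substructure fingerprint as a uint8 bit vector."""
    if n_bits <= 0:
        raise ValidationError(f"fingerprint width must be positive, got {n_bits}")
    fp = Chem.RDKFingerprint(mol, maxPath=max_path, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def parse_molecule(smiles: str, n_bits: int = DEFAULT_FP_BITS) -> Molecule:
    """Parse a SMILES string into a canonical, fingerprinted Molecule.

    Raises :class:`ValidationError` for an empty string and
    :class:`MoleculeParseError` (naming the string) for invalid SMILES.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValidationError("SMILES string is empty")
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise MoleculeParseError(smiles)
    return Molecule(
        smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(rd),
        fingerprint=compute_fingerprint(rd, n_bits=n_bits),
        heavy_atom_count=rd.GetNumHeavyAtoms(),
    )


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def read_smiles_list(path) -> list[str]:
    """Read a plain one-SMILES-per-line file, skipping blank lines."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def read_formulation_table(path, n_bits: int = DEFAULT_FP_BITS) -> list[Formulation]:
    """Read a formulation CSV into Formulation records.

    Rows with a blank or unparseable SMILES cell yield an Ingredient with an
    absent molecule (undefined structure) rather than failing; a warning names
    the offending SMILES.  Non-numeric concentrations raise a row-level error
    carrying the row index.
    """
    df = pd.read_csv(path, dtype={"formulation_id": str, "smiles": str})
    missing = [c for c in FORMULATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing, str(path))
    has_label = "ghs_label" in df.columns

    by_id: dict[str, Formulation] = {}
    for idx, row in df.iterrows():
        try:
            conc = float(row["concentration_pct"])
        except (TypeError, ValueError):
            raise TableRowError(
                int(idx), f"non-numeric concentration {row['concentration_pct']!r}"
            ) from None
        smiles = row["smiles"]
        molecule = None
        if not _is_blank(smiles):
            try:
                molecule = parse_molecule(str(smiles), n_bits=n_bits)
            except MoleculeParseError:
                warnings.warn(
                    f"row {idx}: unparseable SMILES {smiles!r}; "
                    "treating ingredient as undefined structure",
                    stacklevel=2,
                )
        ing = Ingredient(
            name=str(row["ingredient_name"]), molecule=molecule, concentration=conc
        )
        fid = str(row["formulation_id"])
        label = None
        if has_label and not _is_blank(row.get("ghs_label")):
            label = str(row["ghs_label"])
        if fid in by_id:
            by_id[fid].ingredients.append(ing)
            if label is not None:
                by_id[fid].ghs_label = label
        else:
            by_id[fid] = Formulation(id=fid, ingredients=[ing], ghs_label=label)
    return list(by_id.values())


def _parse_mit(value, idx: int) -> Optional[HclatResult]:
    if _is_blank(value):
        return None
    if isinstance(value, str) and value.strip().lower() in ("negative", "neg", "n"):
        return HclatResult(mit=None)
    try:
        return HclatResult(mit=float(value))
    except (TypeError, ValueError):
        raise TableRowError(idx, f"h-CLAT MIT {value!r} is neither a number nor 'negative'") from None


def read_assay_table(path) -> dict[str, AssayPanel]:
    """Read an assay CSV into a mapping of formulation id to AssayPanel.

    Blank DPRA or h-CLAT cells make the corresponding component absent
    (propagating to the range rule downstream); the optional ``ghs_label`` and
    ``insilico_call`` columns are picked up when present.
    """
    df = pd.read_csv(path, dtype={"formulation_id": str})
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing, str(path))

    panels: dict[str, AssayPanel] = {}
    for idx, row in df.iterrows():
        fid = str(row["formulation_id"])
        dpra = None
        if not _is_blank(row["dpra_cys_depletion_pct"]):
            try:
                cys = float(row["dpra_cys_depletion_pct"])
                coel = bool(int(row["dpra_lys_coelution"])) if not _is_blank(
                    row["dpra_lys_coelution"]
                ) else False
                lys = None
                if not _is_blank(row["dpra_lys_depletion_pct"]):
                    lys = float(row["dpra_lys_depletion_pct"])
            except (TypeError, ValueError) as exc:
                raise TableRowError(int(idx), f"bad DPRA values ({exc})") from None
            dpra = DpraResult(cys_depletion=cys, lys_depletion=lys, lys_coelution=coel)
        hclat = _parse_mit(row["hclat_mit_ug_ml"], int(idx))
        label = None
        if "ghs_label" in df.columns and not _is_blank(row.get("ghs_label")):
            label = str(row["ghs_label"])
        call = None
        if "insilico_call" in df.columns and not _is_blank(row.get("insilico_call")):
            call = str(row["insilico_call"]).strip().lower()
            if call not in ("positive", "negative", "missing"):
                raise TableRowError(int(idx), f"bad insilico_call {row['insilico_call']!r}")
        panels[fid] = AssayPanel(
            formulation_id=fid, dpra=dpra, hclat=hclat, ghs_label=label, insilico_call=call
        )
    return panels


def write_formulation_table(formulations: list[Formulation], path) -> None:
    """Write Formulation records back to the formulation CSV format."""
    rows = []
    for f in formulations:
        for ing in f.ingredients:
            rows.append(
                {
                    "formulation_id": f.id,
                    "ingredient_name": ing.name,
                    "smiles": ing.molecule.smiles if ing.molecule is not None else "",
                    "concentration_pct": ing.concentration,
                    "ghs_label": f.ghs_label if f.ghs_label is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(results: dict[str, ItsResult], path) -> None:
    """Write per-substance ITS results to CSV (one row per substance)."""
    rows = []
    for sid, res in results.items():
        rows.append(
            {
                "formulation_id": sid,
                "dpra_score": res.dpra_score if res.dpra_score is not None else "",
                "hclat_score": res.hclat_score if res.hclat_score is not None else "",
                "insilico_score": res.insilico_score if res.insilico_score is not None else "",
                "total_min": res.total_min,
                "total_max": res.total_max,
                "hazard": res.hazard,
                "potency": res.potency,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
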