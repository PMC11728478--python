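"""Deterministic synthetic-data generators for every input the pipeline consumes.

Three kinds of inputs are emulated so the whole tool can be exercised with no
external downloads:

* small organic molecules assembled from a fragment grammar, a configurable
  fraction carrying a planted isothiocyanate "structural alert" (a reactive
  electrophilic group, here the marker that drives synthetic labels),
* multitask training sets with the four-task structure (protein binding,
  keratinocyte activation, dendritic-cell activation, human sensitization)
  whose labels follow one shared Boolean rule over fingerprint bits plus
  per-task label noise,
* formulation panels in the package's CSV formats, with per-formulation DPRA
  and h-CLAT values drawn inside the score bin that realizes each planted
  GHS label, so a noise-free panel is recovered exactly by the ITS cutoffs.

Everything is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .chemio import Molecule, parse_molecule
from .errors import ValidationError
from .mtxtrees import TASKS, TaskDataset

# Chain-extensible fragments: each may be concatenated after any other and
# still yield valid SMILES (no terminal halogens, no pending ring bonds).
_FRAGMENTS = (
    "C", "CC", "CCC", "CO", "CN", "C(C)C", "C(=O)C", "COC",
    "Cc1ccccc1", "CCO", "C(C)(C)C", "c1ccccc1",
)
ALERT_SMILES = "CN=C=S"          # planted structural alert (isothiocyanate), terminal
ALERT_SUBSTRUCTURE = "N=C=S"


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for a synthetic formulation panel.

    Default class mix mirrors the benchmark panel of 27 agrochemical
    formulations: 15 nonsensitizers, 11 weak/moderate (1B) and 1 strong (1A)
    sensitizer.  ``noise`` is the per-component probability that a planted
    assay score bin is replaced by a uniformly random one.
    """

    n_formulations: int = 27
    class_mix: dict = field(default_factory=lambda: {"NC": 15, "1B": 11, "1A": 1})
    noise: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if sum(self.class_mix.values()) != self.n_formulations:
            raise ValidationError("class_mix counts must sum to n_formulations")
        if not 0.0 <= self.noise <= 1.0:
            raise ValidationError("noise must lie in [0, 1]")


def generate_smiles(n: int, seed: int, alert_fraction: float = 0.5) -> list[str]:
    """Generate ``n`` valid SMILES strings, ``alert_fraction`` of them alerts."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        k = int(rng.integers(2, 5))
        body = "".join(rng.choice(_FRAGMENTS, size=k))
        if rng.random() < alert_fraction:
            body += ALERT_SMILES
        out.append(body)
    return out


def generate_molecules(
    n: int, seed: int, alert_fraction: float = 0.5, n_bits: int = 1024
) -> list[Molecule]:
    """Generate ``n`` parsed, fingerprinted molecules (deterministic per seed)."""
    return [parse_molecule(s, n_bits=n_bits) for s in generate_smiles(n, seed, alert_fraction)]


def has_alert(mol: Molecule) -> bool:
    """Whether a molecule carries the planted alert substructure."""
    from rdkit import Chem

    query = Chem.MolFromSmarts(ALERT_SUBSTRUCTURE)
    return Chem.MolFromSmiles(mol.canonical_smiles).HasSubstructMatch(query)


@dataclass
class MultitaskData:
    """A synthetic multitask dataset with its recorded ground truth."""

    dataset: TaskDataset
    rule_bits: tuple[int, int]
    true_labels: np.ndarray  # noise-free labels, aligned with dataset rows


def _rule_labels(X: np.ndarray, rule_bits: tuple[int, int]) -> np.ndarray:
    a, b = rule_bits
    return (X[:, a] & X[:, b]).astype(np.int8)


def generate_multitask_dataset(
    n_per_task: int = 50,
    n_bits: int = 32,
    tasks: tuple[str, ...] = TASKS,
    rule_bits: tuple[int, int] = (7, 13),
    noise: float = 0.2,
    seed: int = 0,
) -> MultitaskData:
    """Random binary features; labels = (bit AND bit) shared across tasks.

    Each task receives independent feature draws from the same distribution
    and its labels are flipped independently with probability ``noise``.
    """
    if not tasks or n_per_task < 1:
        raise ValidationError("need >= 1 task and >= 1 sample per task")
    rng = np.random.default_rng(seed)
    feats, labels, noisy, ids = [], [], [], []
    for task in tasks:
        X = (rng.random((n_per_task, n_bits)) < 0.5).astype(np.uint8)
        y = _rule_labels(X, rule_bits)
        flips = rng.random(n_per_task) < noise
        feats.append(X)
        labels.append(y)
        noisy.append(np.where(flips, 1 - y, y))
        ids.extend([task] * n_per_task)
    data = TaskDataset(
        features=np.vstack(feats),
        labels=np.concatenate(noisy),
        task_ids=np.array(ids, dtype=object),
    )
    return MultitaskData(dataset=data, rule_bits=rule_bits,
                         true_labels=np.concatenate(labels))


# --- formulation panels -----------------------------------------------------

# DPRA mean-depletion sampling windows per score (open just below upper bins
# so a drawn value always bins back to its score).
_DPRA_WINDOWS = ((0.0, 6.37), (6.38, 22.61), (22.62, 42.46), (42.47, 100.0))
_MIT_WINDOWS = (None, (151.0, 5000.0), (10.5, 150.0), (0.5, 10.0))

_LABEL_TOTALS = {"NC": (0, 1), "1B": (2, 5), "1A": (6, 7)}


def _decompositions(total: int) -> list[tuple[int, int, int]]:
    return [
        (d, h, i)
        for d in range(4)
        for h in range(4)
        for i in range(2)
        if d + h + i == total
    ]


@dataclass
class FormulationPanel:
    """A generated panel: the two CSV tables plus the planted truth labels."""

    formulations: pd.DataFrame
    assays: pd.DataFrame
    truth: dict[str, str]
    planted_scores: dict[str, tuple[int, int, int]]

    def write(self, outdir) -> tuple[Path, Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fpath = outdir / "formulations.csv"
        apath = outdir / "assays.csv"
        tpath = outdir / "truth.csv"
        self.formulations.to_csv(fpath, index=False)
        self.assays.to_csv(apath, index=False)
        pd.DataFrame(
            {"formulation_id": list(self.truth), "ghs_label": list(self.truth.values())}
        ).to_csv(tpath, index=False)
        return fpath, apath, tpath


def generate_formulation_panel(spec: Optional[PanelSpec] = None) -> FormulationPanel:
    """Generate a formulation panel whose assay values encode planted GHS labels.

    For each formulation a target total score is drawn inside the planted
    label's range, decomposed into (DPRA, h-CLAT, in silico) components, and
    raw assay values are sampled uniformly inside the corresponding score
    bin.  With ``noise`` > 0 each component's score bin is, with that
    probability, replaced by a uniformly random bin before sampling, so
    recovery accuracy degrades with noise.  Ingredient lists are synthetic
    molecules; a formulation with a positive in silico component gets an
    alert-carrying ingredient above the 0.1 % concentration cutoff, and the
    final per-formulation call is recorded in the ``insilico_call`` column.
    """
    if spec is None:
        spec = PanelSpec()
    rng = np.random.default_rng(spec.rng_seed)
    labels = [lab for lab, cnt in spec.class_mix.items() for _ in range(cnt)]
    rng.shuffle(labels)

    smiles_pool_plain = generate_smiles(200, seed=int(rng.integers(2**31)), alert_fraction=0.0)
    alert_pool = [s + ALERT_SMILES for s in smiles_pool_plain[:50]]

    frm_rows, assay_rows = [], []
    truth: dict[str, str] = {}
    planted: dict[str, tuple[int, int, int]] = {}
    for idx, label in enumerate(labels, start=1):
        fid = f"F{idx:03d}"
        lo, hi = _LABEL_TOTALS[label]
        total = int(rng.integers(lo, hi + 1))
        options = _decompositions(total)
        d, h, i = options[int(rng.integers(len(options)))]
        # component-wise score noise
        if rng.random() < spec.noise:
            d = int(rng.integers(0, 4))
        if rng.random() < spec.noise:
            h = int(rng.integers(0, 4))
        if rng.random() < spec.noise:
            i = int(rng.integers(0, 2))
        planted[fid] = (d, h, i)

        dlo, dhi = _DPRA_WINDOWS[d]
        mean = float(rng.uniform(dlo, dhi))
        if h == 0:
            mit = "negative"
        else:
            mlo, mhi = _MIT_WINDOWS[h]
            mit = round(float(rng.uniform(mlo, mhi)), 2)
        assay_rows.append(
            {
                "formulation_id": fid,
                "dpra_cys_depletion_pct": round(mean, 2),
                "dpra_lys_depletion_pct": round(mean, 2),
                "dpra_lys_coelution": 0,
                "hclat_mit_ug_ml": mit,
                "insilico_call": "positive" if i == 1 else "negative",
                "ghs_label": label,
            }
        )
        truth[fid] = label

        n_ing = int(rng.integers(1, 4))
        concs = np.round(rng.uniform(1.0, 30.0, size=n_ing), 2)
        ing_smiles = [
            smiles_pool_plain[int(rng.integers(len(smiles_pool_plain)))]
            for _ in range(n_ing)
        ]
        if i == 1:  # plant an alert ingredient above the concentration cutoff
            ing_smiles[0] = alert_pool[int(rng.integers(len(alert_pool)))]
            concs[0] = max(concs[0], 0.5)
        for j, (smi, conc) in enumerate(zip(ing_smiles, concs), start=1):
            frm_rows.append(
                {
                    "formulation_id": fid,
                    "ingredient_name": f"{fid}-ing{j}",
                    "smiles": smi,
                    "concentration_pct": conc,
                    "ghs_label": label,
                }
            )

    return FormulationPanel(
        formulations=pd.DataFrame(frm_rows),
        assays=pd.DataFrame(assay_rows),
        truth=truth,
        planted_scores=planted,
    )


def generate_concordance_table(
    n: int = 60, seed: int = 0, alert_fraction: float = 0.5, n_bits: int = 1024
) -> pd.DataFrame:
    """Concordance records where exactly the alert carriers are discordant.

    Emulates the pesticide benchmark used to derive exclusion rules: animal
    call and in silico call agree except on molecules carrying the planted
    alert substructure.
    """
    rng = np.random.default_rng(seed)
    classes = ("herbicide", "fungicide", "insecticide")
    rows = []
    for smi in generate_smiles(n, seed=seed + 1, alert_fraction=alert_fraction):
        mol = parse_molecule(smi, n_bits=n_bits)
        discordant = has_alert(mol)
        animal = "positive" if rng.random() < 0.5 else "negative"
        insilico = ("negative" if animal == "positive" else "positive") if discordant else animal
        rows.append(
            {
                "smiles": smi,
                "insilico_call": insilico,
                "animal_call": animal,
                "pesticide_class": classes[int(rng.integers(3))],
            }
        )
    return pd.DataFrame(rows)


def synthetic_reference_panel() -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic stand-in for the 27-formulation agrochemical benchmark panel.

    The real panel (per-formulation DPRA/h-CLAT results, in silico calls and
    in vivo GHS labels) is not redistributable, so this fixture is a
    *synthetic* reconstruction: 27 rows with the benchmark's class mix
    (15 NC / 11 1B / 1 1A) whose assay values and in silico calls realize the
    benchmark's derived confusion structure — 20 conclusive hazard calls
    (TP=8, FN=1, TN=5, FP=6) and 17 conclusive potency calls (10 correct,
    1 under, 6 over).  Raw assay values are placed mid-bin so the full
    scoring pipeline (not just the totals) reproduces the intended scores.
    """
    # (truth, dpra_score, hclat_score, insilico_call)
    plan = [
        # 5 true positives with conclusive, correct 1B potency
        ("1B", 1, 1, "negative"), ("1B", 2, 2, "positive"), ("1B", 1, 2, "positive"),
        ("1B", 2, 1, "negative"), ("1B", 1, 1, "positive"),
        # 3 true positives, hazard conclusive but potency straddles 1B/1A
        ("1A", 3, 2, "missing"), ("1B", 3, 2, "missing"), ("1B", 3, 2, "missing"),
        # 1 false negative (conclusive NC; potency underprediction)
        ("1B", 0, 1, "negative"),
        # 3 sensitizers left inconclusive
        ("1B", 0, 1, "missing"), ("1B", 0, 1, "missing"), ("1B", 0, 1, "missing"),
        # 5 true negatives
        ("NC", 0, 0, "negative"), ("NC", 0, 1, "negative"), ("NC", 0, 0, "negative"),
        ("NC", 0, 1, "negative"), ("NC", 0, 0, "negative"),
        # 6 false positives (overpredicted to 1B)
        ("NC", 1, 1, "negative"), ("NC", 1, 0, "positive"), ("NC", 2, 0, "negative"),
        ("NC", 0, 2, "negative"), ("NC", 1, 1, "negative"), ("NC", 2, 0, "negative"),
        # 4 nonsensitizers left inconclusive
        ("NC", 1, 0, "missing"), ("NC", 0, 1, "missing"),
        ("NC", 1, 0, "missing"), ("NC", 0, 1, "missing"),
    ]
    dpra_value = {0: 5.0, 1: 15.0, 2: 30.0, 3: 60.0}
    mit_value = {0: "negative", 1: 2000.0, 2: 100.0, 3: 5.0}
    rows = []
    truth = {}
    for idx, (label, d, h, call) in enumerate(plan, start=1):
        fid = f"R{idx:02d}"
        rows.append(
            {
                "formulation_id": fid,
                "dpra_cys_depletion_pct": dpra_value[d],
                "dpra_lys_depletion_pct": dpra_value[d],
                "dpra_lys_coelution": 0,
                "hclat_mit_ug_ml": mit_value[h],
                "insilico_call": call,
                "ghs_label": label,
            }
        )
        truth[fid] = label
    return pd.DataFrame(rows), truth
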