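"""Biophysical annotation of contacts and sequences.

Each contact can be scored by the summed Kyte-Doolittle hydropathy of its
two residues (positive = hydrophobic pair), flagged as a charged contact
when its residues carry opposite charges, and assigned a knowledge-based
pair energy from a symmetric 20x20 contact-potential table (attractive =
negative).  Sequence-level disorder propensity is summarised by the
fractions of disorder-promoting (DPR) and order-promoting (OPR) residues.

The default pair-energy table shipped with the package
(``data/synthetic_contact_potential.tsv``) is a synthetic stand-in built
from hydropathy and charge complementarity; any symmetric 20x20 table in
the same TSV format can be substituted via :func:`load_pair_energy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import ranksums

from .contacts import Contact, LifetimeTable, as_contact

__all__ = [
    "ResidueScales",
    "load_scales",
    "load_pair_energy",
    "hydropathy_score",
    "charged_contact_ratio",
    "contact_energy",
    "dpr_opr_content",
    "hydropathy_heatmap_table",
    "annotate_contacts",
    "compare_populations",
    "read_fasta_sequence",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ResidueScales:
    """Per-amino-acid scales: hydropathy, charge, disorder propensity,
    and a symmetric pair-energy table."""

    hydropathy: dict[str, float]
    charge: dict[str, str]          # aa -> "+", "-", "0"
    promoting: dict[str, str]       # aa -> "disorder", "order", "neutral"
    pair_energy: pd.DataFrame       # 20x20 symmetric

    def __post_init__(self) -> None:
        for name, scale in (
            ("hydropathy", self.hydropathy),
            ("charge", self.charge),
            ("promoting", self.promoting),
        ):
            missing = STANDARD_AA - set(scale)
            if missing:
                raise ValueError(f"{name} scale misses residues {sorted(missing)}")
        e = self.pair_energy
        if set(e.index) != STANDARD_AA or set(e.columns) != STANDARD_AA:
            raise ValueError("pair-energy table must cover the 20 standard residues")
        if not np.allclose(e.values, e.values.T):
            raise ValueError("pair-energy table must be symmetric")


def load_pair_energy(path: str | Path | None = None) -> pd.DataFrame:
    """Load a symmetric 20x20 pair-energy TSV (default: the packaged
    synthetic table)."""
    if path is None:
        ref = resources.files("ctidp.data") / "synthetic_contact_potential.tsv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    else:
        table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    table.index = table.index.astype(str)
    return table


def load_scales(
    scales_path: str | Path | None = None,
    pair_energy_path: str | Path | None = None,
    histidine_positive: bool = False,
) -> ResidueScales:
    """Load residue scales from YAML (+ pair-energy TSV).

    ``histidine_positive`` promotes His from neutral to "+".
    """
    if scales_path is None:
        ref = resources.files("ctidp.data") / "scales.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(scales_path).read_text())
    charge = {aa: "0" for aa in STANDARD_AA}
    for aa in raw["charge"]["negative"]:
        charge[aa] = "-"
    for aa in raw["charge"]["positive"]:
        charge[aa] = "+"
    if histidine_positive:
        charge["H"] = "+"
    promoting = {aa: "neutral" for aa in STANDARD_AA}
    for cls in ("disorder", "order"):
        for aa in raw["promoting"][cls]:
            promoting[aa] = cls
    return ResidueScales(
        hydropathy={k: float(v) for k, v in raw["hydropathy"].items()},
        charge=charge,
        promoting=promoting,
        pair_energy=load_pair_energy(pair_energy_path),
    )


_DEFAULT: ResidueScales | None = None


def default_scales() -> ResidueScales:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_scales()
    return _DEFAULT


def _residue(sequence: str, index: int) -> str:
    if not 1 <= index <= len(sequence):
        raise ValueError(
            f"residue index {index} outside sequence of length {len(sequence)}"
        )
    aa = sequence[index - 1].upper()
    if aa not in STANDARD_AA:
        raise ValueError(f"nonstandard residue {aa!r} at position {index}")
    return aa


def hydropathy_score(
    contact: Contact | tuple, sequence: str, scales: ResidueScales | None = None
) -> float:
    """Sum of the two residues' hydropathy indices; positive = hydrophobic
    pair."""
    scales = scales or default_scales()
    c = as_contact(*contact)
    return scales.hydropathy[_residue(sequence, c.i)] + scales.hydropathy[
        _residue(sequence, c.j)
    ]


def charged_contact_ratio(
    contacts: Iterable[Contact | tuple],
    sequence: str,
    scales: ResidueScales | None = None,
) -> float:
    """Fraction of contacts formed by opposite-charge residue pairs."""
    scales = scales or default_scales()
    contacts = [as_contact(*c) for c in contacts]
    if not contacts:
        raise ValueError("empty contact set")
    charged = 0
    for c in contacts:
        qa = scales.charge[_residue(sequence, c.i)]
        qb = scales.charge[_residue(sequence, c.j)]
        if {qa, qb} == {"+", "-"}:
            charged += 1
    return charged / len(contacts)


def contact_energy(
    contact: Contact | tuple,
    sequence: str,
    table: pd.DataFrame | None = None,
) -> float:
    """Pair-potential energy of a contact (symmetric lookup; attractive =
    negative)."""
    if table is None:
        table = default_scales().pair_energy
    c = as_contact(*contact)
    aa_i = _residue(sequence, c.i)
    aa_j = _residue(sequence, c.j)
    try:
        return float(table.loc[aa_i, aa_j])
    except KeyError as err:
        raise KeyError(f"pair-energy table misses entry ({aa_i}, {aa_j})") from err


def dpr_opr_content(
    sequence: str, scales: ResidueScales | None = None
) -> tuple[float, float]:
    """(disorder-promoting, order-promoting) residue fractions of a
    sequence; neutral residues count in neither numerator."""
    scales = scales or default_scales()
    if not sequence:
        raise ValueError("empty sequence")
    classes = [scales.promoting[_residue(sequence, k)] for k in range(1, len(sequence) + 1)]
    n = len(sequence)
    return (classes.count("disorder") / n, classes.count("order") / n)


def hydropathy_heatmap_table(
    contacts: Iterable[Contact | tuple],
    sequence: str,
    scales: ResidueScales | None = None,
) -> pd.DataFrame:
    """Per-contact (res_i, res_j, hydropathy) records, ready for plotting."""
    scales = scales or default_scales()
    rows = [
        (c.i, c.j, hydropathy_score(c, sequence, scales))
        for c in sorted(as_contact(*c) for c in contacts)
    ]
    return pd.DataFrame(rows, columns=["res_i", "res_j", "hydropathy"])


def annotate_contacts(
    lifetimes: LifetimeTable,
    sequence: str,
    scales: ResidueScales | None = None,
) -> pd.DataFrame:
    """Full annotation table: residues, hydropathy, energy, charge flag
    and regime for every contact in a lifetime table."""
    scales = scales or default_scales()
    rows = []
    for i, j, lt, regime in lifetimes.table[
        ["res_i", "res_j", "lifetime_ns", "regime"]
    ].itertuples(index=False):
        c = as_contact(i, j)
        aa_i = _residue(sequence, c.i)
        aa_j = _residue(sequence, c.j)
        qset = {scales.charge[aa_i], scales.charge[aa_j]}
        rows.append(
            (
                c.i,
                c.j,
                aa_i,
                aa_j,
                scales.hydropathy[aa_i] + scales.hydropathy[aa_j],
                float(scales.pair_energy.loc[aa_i, aa_j]),
                qset == {"+", "-"},
                lt,
                regime,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "res_i", "res_j", "aa_i", "aa_j",
            "hydropathy", "energy", "charged", "lifetime_ns", "regime",
        ],
    )


def compare_populations(
    a: Sequence[float],
    b: Sequence[float],
    n_subsample: int = 300,
    n_extractions: int = 20,
    seed: int | None = None,
) -> list[float]:
    """Rank-sum p-values over repeated random subsamples of two
    populations (default: 20 extractions of 300 points each); populations
    smaller than the subsample are used whole."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pvals = []
    for _ in range(n_extractions):
        xa = rng.choice(a, size=min(n_subsample, a.size), replace=False)
        xb = rng.choice(b, size=min(n_subsample, b.size), replace=False)
        pvals.append(float(ranksums(xa, xb).pvalue))
    return pvals


def read_fasta_sequence(path: str | Path) -> str:
    """First sequence of a FASTA file, as a plain string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
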