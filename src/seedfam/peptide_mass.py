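"""Monoisotopic mass prediction for seed-albumin buried peptides (PDPs).

PawS-derived peptides are backbone-cyclic (head-to-tail, losing one water)
and carry a single disulfide bond between their two conserved Cys residues
(losing two hydrogens relative to the reduced form).  LC-MS detects them as
multiply protonated ions, conventionally the doubly charged [M+2H]2+.
This module predicts those m/z values from annotated precursor sequences and
matches them against an observed mass list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mass as _pmass

#: monoisotopic mass of one water molecule (Da); removed by backbone cyclisation
WATER = 18.010565
#: monoisotopic proton mass (Da)
PROTON = 1.007276
#: monoisotopic hydrogen-atom mass (Da); a disulfide bond removes two
HYDROGEN = 1.0078250319

#: standard monoisotopic residue masses (Da), 20 canonical amino acids
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}


@dataclass(frozen=True)
class PeptideIonSpec:
    """A peptide together with the conventions used to compute its ion m/z.

    Parameters
    ----------
    sequence : str
        Protein sequence over the 20 canonical residues.
    cyclic : bool
        Head-to-tail backbone cyclisation (removes one water).
    n_disulfides : int
        Number of disulfide bonds (each removes two hydrogens).
    charge : int
        Positive charge state of the ion.
    """

    sequence: str
    cyclic: bool = False
    n_disulfides: int = 0
    charge: int = 2

    def __post_init__(self) -> None:
        bad = sorted({c for c in self.sequence if c not in RESIDUE_MASS})
        if bad:
            raise ValueError(f"non-canonical residue(s): {','.join(bad)}")
        if self.n_disulfides < 0:
            raise ValueError("n_disulfides must be >= 0")
        if self.n_disulfides > self.sequence.count("C") // 2:
            raise ValueError("n_disulfides exceeds floor(Cys count / 2)")
        if self.cyclic and len(self.sequence) < 3:
            raise ValueError("cyclic peptides need length >= 3")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class MassMatch:
    sequence: str
    predicted_mz: float
    observed_mz: float | None
    delta: float | None
    within_tolerance: bool


def neutral_monoisotopic_mass(spec: PeptideIonSpec) -> float:
    """Neutral monoisotopic mass (Da) of a peptide under the given conventions.

    Linear peptides carry one water (N-terminal H, C-terminal OH); head-to-tail
    cyclisation condenses it out.  Each disulfide bond (oxidised Cys pair)
    removes two hydrogen atoms.
    """
    m = sum(RESIDUE_MASS[aa] for aa in spec.sequence)
    if not spec.cyclic:
        m += WATER
    m -= spec.n_disulfides * 2 * HYDROGEN
    return m


def ion_mz(neutral_mass: float, charge: int) -> float:
    """m/z of the [M+zH]z+ ion for a neutral monoisotopic mass."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def predicted_mz(spec: PeptideIonSpec) -> float:
    """Convenience composition: neutral mass then protonated ion m/z."""
    return ion_mz(neutral_monoisotopic_mass(spec), spec.charge)


def predict_pdp_ion_table(
    annotations: Iterable,
    charge: int = 2,
    include_pawl: bool = False,
) -> pd.DataFrame:
    """Build the predicted-ion table for the unique PDPs of a set of precursors.

    PawS-type PDPs (two Cys) are predicted as backbone-cyclic with one
    disulfide, the mature form detected in seed extracts.  PawL-type buried
    regions (no Cys) do not yield a stable peptide and are excluded unless
    ``include_pawl`` is set.  PDPs repeated within or across genes are
    reported once.

    ``annotations`` may be PrecursorAnnotation objects (with ``.pdp_sequence``
    and ``.pdp_cys_count``) or plain PDP sequence strings.
    """
    rows = []
    seen: set[str] = set()
    for ann in annotations:
        seq = ann if isinstance(ann, str) else getattr(ann, "pdp_sequence", None)
        if not seq or seq in seen:
            continue
        seen.add(seq)
        n_cys = seq.count("C")
        if n_cys == 0 and not include_pawl:
            continue
        warning = ""
        if n_cys % 2 == 1:
            n_ss = 0
            warning = "odd-cys-count"
        else:
            n_ss = n_cys // 2
        cyclic = n_cys >= 2
        spec = PeptideIonSpec(seq, cyclic=cyclic, n_disulfides=n_ss, charge=charge)
        rows.append(
            {
                "sequence": seq,
                "cyclic": cyclic,
                "n_disulfides": n_ss,
                "charge": charge,
                "predicted_mz": round(predicted_mz(spec) + 1e-9, 2),
                "warning": warning,
            }
        )
    rows.sort(key=lambda r: r["sequence"])
    return pd.DataFrame(
        rows,
        columns=["sequence", "cyclic", "n_disulfides", "charge", "predicted_mz", "warning"],
    )


def match_observed(
    predicted: pd.DataFrame,
    observed_mz: Sequence[float],
    tolerance: float = 0.05,
) -> tuple[list[MassMatch], int]:
    """Match each predicted ion to the nearest observed m/z.

    Returns the per-row matches and the count of rows whose nearest observed
    mass lies within ``tolerance`` Da.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    matches: list[MassMatch] = []
    n_matched = 0
    for _, row in predicted.iterrows():
        if len(observed_mz) == 0:
            matches.append(MassMatch(row["sequence"], row["predicted_mz"], None, None, False))
            continue
        nearest = min(observed_mz, key=lambda o: abs(o - row["predicted_mz"]))
        delta = abs(nearest - row["predicted_mz"])
        ok = delta <= tolerance
        n_matched += ok
        matches.append(MassMatch(row["sequence"], row["predicted_mz"], nearest, delta, ok))
    return matches, n_matched


def read_observed_masses(path) -> list[float]:
    """Read an observed-mass list: one m/z per line, optionally followed by a
    retention time column (TSV); '#' lines are comments."""
    out: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(float(line.split("\t")[0]))
    return out
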