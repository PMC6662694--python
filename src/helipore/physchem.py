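"""Sequence-level physico-chemical descriptors of helical peptides.

Net charge at neutral pH, mean hydrophobicity ⟨H⟩ and the helical
hydrophobic moment μH in the HeliQuest convention: residue hydrophobicities
(Fauchère–Pliška octanol/water scale by default) are placed at 100°
azimuthal increments around an ideal α-helix and vector-summed; the
normalized magnitude of that sum measures secondary amphipathicity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Fauchère & Pliška (1983) octanol/water side-chain hydrophobicities,
#: the scale used by HeliQuest.
FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: Side-chain formal charges at neutral pH (His treated as neutral).
SIDECHAIN_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1, "H": 0}


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a non-canonical one-letter code."""


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named per-residue hydrophobicity table covering all 20 amino acids."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = CANONICAL_AA - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")

    def __getitem__(self, code: str) -> float:
        return self.values[code]


DEFAULT_SCALE = HydrophobicityScale("Fauchere-Pliska", FAUCHERE_PLISKA)


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide as one-letter residues plus terminal chemistry.

    Both study peptides (aurein 2.5 and temporin L) carry a free N-terminus
    and an amidated C-terminus, which removes the C-terminal negative charge.
    """

    id: str
    residues: str
    n_term_free: bool = True
    c_term_amidated: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("empty sequence")
        bad = set(self.residues) - CANONICAL_AA
        if bad:
            raise UnknownResidueError(
                f"{self.id}: non-canonical residue code(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


# the two study peptides (C-terminally amidated)
AUREIN_25 = PeptideSequence("aurein_2.5", "GLFDIVKKVVGAFGSL", c_term_amidated=True)
TEMPORIN_L = PeptideSequence("temporin_L", "FVQWFSKFLGRIL", c_term_amidated=True)


@dataclass(frozen=True)
class PhyschemProfile:
    """Computed descriptors for one peptide."""

    id: str
    length: int
    net_charge: int
    mean_hydrophobicity: float
    hydrophobic_moment: float
    delta_angle: float = 100.0
    scale: str = DEFAULT_SCALE.name

    def as_dict(self) -> dict:
        return {
            "id": self.id,
            "length": self.length,
            "net_charge": self.net_charge,
            "mean_hydrophobicity": round(self.mean_hydrophobicity, 3),
            "hydrophobic_moment": round(self.hydrophobic_moment, 3),
            "delta_angle": self.delta_angle,
            "scale": self.scale,
        }


def net_charge(seq: PeptideSequence) -> int:
    """Formal charge at neutral pH: side chains (K,R → +1; D,E → −1; H → 0)
    plus +1 for a free N-terminus and −1 for a free-acid C-terminus."""
    q = sum(SIDECHAIN_CHARGE.get(aa, 0) for aa in seq.residues)
    if seq.n_term_free:
        q += 1
    if not seq.c_term_amidated:
        q -= 1
    return q


def mean_hydrophobicity(
    seq: PeptideSequence, scale: HydrophobicityScale = DEFAULT_SCALE
) -> float:
    """Length-normalized sum of per-residue hydrophobicities, ⟨H⟩."""
    return sum(scale[aa] for aa in seq.residues) / len(seq)


def hydrophobic_moment(
    seq: PeptideSequence,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    delta: float = 100.0,
) -> float:
    """Helical hydrophobic moment μH.

    μH = (1/N)·|Σᵢ H(aaᵢ)·exp(i·j·δ)| with residue j at azimuth j·δ
    (j = 0..N−1, δ in degrees, default 100° for an ideal α-helix).
    The magnitude is independent of the phase origin.
    """
    d = math.radians(delta)
    cx = sum(scale[aa] * math.cos(j * d) for j, aa in enumerate(seq.residues))
    cy = sum(scale[aa] * math.sin(j * d) for j, aa in enumerate(seq.residues))
    return math.hypot(cx, cy) / len(seq)


def physchem_profile(
    seq: PeptideSequence,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    delta: float = 100.0,
) -> PhyschemProfile:
    return PhyschemProfile(
        id=seq.id,
        length=len(seq),
        net_charge=net_charge(seq),
        mean_hydrophobicity=mean_hydrophobicity(seq, scale),
        hydrophobic_moment=hydrophobic_moment(seq, scale, delta),
        delta_angle=delta,
        scale=scale.name,
    )


def read_fasta(path: str | Path, c_term_amidated: bool = False) -> list[PeptideSequence]:
    """Read peptide sequences from a FASTA file.

    Terminal chemistry is not representable in FASTA; ``c_term_amidated``
    applies to every record (override per sequence via the API if mixed).
    """
    return [
        PeptideSequence(rec.id, str(rec.seq).upper(), c_term_amidated=c_term_amidated)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def profile_table(profiles: Iterable[PhyschemProfile]) -> pd.DataFrame:
    """Tabulate profiles as (id, length, charge, H, μH) with 3-decimal values."""
    return pd.DataFrame([p.as_dict() for p in profiles])


def write_report(
    profiles: Iterable[PhyschemProfile], csv_path: str | Path, json_path: str | Path | None = None
) -> pd.DataFrame:
    df = profile_table(profiles)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    return df
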