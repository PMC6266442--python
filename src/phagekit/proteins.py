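"""Translation and theoretical protein descriptors (MW, pI).

MW uses average (not monoisotopic) residue masses, the convention of the
ExPASy Compute pI/MW tool. The isoelectric point is found by bisection on
the protein net charge as a function of pH, using the Bjellqvist pKa set
(termini plus D, E, C, Y, H, K, R side chains); the net charge is a
strictly decreasing function of pH, so the root is unique. The initial
methionine is retained (no N-terminal excision).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ._round import round_half_up

__all__ = [
    "ProteinRecord",
    "PrematureStopError",
    "AmbiguousCodonError",
    "translate",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "BJELLQVIST_PKA",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# Bjellqvist pKa values (ExPASy defaults). Side chains carry the charge sign;
# termini are residue-independent here except where Bjellqvist specifies.
BJELLQVIST_PKA = {
    "n_term": 7.5,
    "c_term": 3.55,
    "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
}

# Residue-specific N-terminal pKa corrections (Bjellqvist).
_NTERM_BY_RESIDUE = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                     "V": 7.44, "E": 7.7}


class PrematureStopError(ValueError):
    """A stop codon occurs before the final codon."""


class AmbiguousCodonError(ValueError):
    """A codon contains N and cannot be translated."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    mw_kda: float | None = None
    pi: float | None = None

    def __post_init__(self):
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"protein {self.id!r}: unknown residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_features(self) -> "ProteinRecord":
        return ProteinRecord(
            self.id,
            self.sequence,
            mw_kda=molecular_weight(self.sequence),
            pi=isoelectric_point(self.sequence),
        )


def translate(dna: str, treat_start_as_met: bool = True) -> str:
    """Translate a coding sequence (standard bacterial code, table 11).

    A single trailing stop codon is stripped. With ``treat_start_as_met``
    an initial GTG/TTG is read as methionine (start-codon semantics).
    """
    dna = dna.upper().replace("U", "T")
    if len(dna) % 3 != 0:
        raise ValueError(f"length {len(dna)} is not a multiple of 3")
    if "N" in dna:
        idx = dna.index("N") // 3
        raise AmbiguousCodonError(f"codon {idx + 1} contains N")
    aa = str(Seq(dna).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise PrematureStopError(f"internal stop at residue {aa.index('*') + 1}")
    if treat_start_as_met and dna[:3] in ("ATG", "GTG", "TTG") and aa:
        aa = "M" + aa[1:]
    return aa


def molecular_weight(p: str) -> float:
    """Average molecular weight in kDa, half-up to 1 dp."""
    if not p:
        raise ValueError("empty protein")
    bad = set(p) - AA_ALPHABET
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)}")
    return round_half_up(ProteinAnalysis(p).molecular_weight() / 1000.0, 1)


def net_charge(p: str, pH: float) -> float:
    """Protein net charge at a given pH under the Bjellqvist pKa set."""
    if not p:
        raise ValueError("empty protein")

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    charge = pos(_NTERM_BY_RESIDUE.get(p[0], BJELLQVIST_PKA["n_term"]))
    charge += neg(BJELLQVIST_PKA["c_term"])
    for aa, pka in BJELLQVIST_PKA["positive"].items():
        charge += p.count(aa) * pos(pka)
    for aa, pka in BJELLQVIST_PKA["negative"].items():
        charge += p.count(aa) * neg(pka)
    return charge


def isoelectric_point(p: str, tol: float = 1e-6) -> float:
    """pH of zero net charge by bisection, half-up to 2 dp.

    Bisects on [0, 14]; the charge is strictly decreasing in pH so at most
    ~50 iterations reach |charge| < 1e-4 well before the interval tolerance.
    """
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        c = net_charge(p, mid)
        if abs(c) < 1e-12 or hi - lo < tol:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    return round_half_up(0.5 * (lo + hi), 2)
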