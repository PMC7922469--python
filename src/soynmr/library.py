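"""Reference library of soybean 1H-NMR peak assignments.

The library holds the 25 metabolites identified in aqueous-methanol soybean
extracts by 1D 1H-NMR (with COSY/HSQC confirmation): ten amino acids, three
carbohydrates, nine organic acids, one fatty acid and two purine derivatives.
Each entry records the chemical shift (ppm relative to TSP), multiplicity and
scalar coupling constant(s) J in Hz. The library drives both the spectral
simulator (multiplet rendering) and feature aggregation (bin-to-metabolite
assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MetabolitePeak",
    "MetaboliteLibrary",
    "build_metabolite_library",
    "MULTIPLICITIES",
]

#: Recognized multiplicity codes: singlet, doublet, doublet of doublets,
#: triplet, quartet, unresolved multiplet, broad singlet.
MULTIPLICITIES = ("s", "d", "dd", "t", "q", "m", "br_s")

#: Number of J values each multiplicity pattern requires.
_N_J = {"s": 0, "d": 1, "dd": 2, "t": 1, "q": 1, "m": 0, "br_s": 0}


@dataclass(frozen=True)
class MetabolitePeak:
    """One resonance of one metabolite.

    Parameters
    ----------
    metabolite_name : str
        Compound the resonance belongs to.
    center_shift : float
        Chemical shift of the multiplet centre, ppm. Shift ranges reported as
        "a-b" are represented by their midpoint.
    multiplicity : str
        One of :data:`MULTIPLICITIES`.
    j_values : tuple of float
        Coupling constants in Hz; empty for s/m/br_s, one entry for d/t/q,
        two for dd.
    assignment_label : str
        Proton position label (e.g. ``"H-3"``).
    """

    metabolite_name: str
    center_shift: float
    multiplicity: str
    j_values: tuple[float, ...] = ()
    assignment_label: str = ""

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        if not 0.0 <= self.center_shift <= 10.0:
            raise ValueError(
                f"center_shift {self.center_shift} ppm outside [0, 10] "
                f"for {self.metabolite_name}"
            )
        expected = _N_J[self.multiplicity]
        if len(self.j_values) != expected:
            raise ValueError(
                f"{self.metabolite_name} at {self.center_shift} ppm: "
                f"multiplicity {self.multiplicity!r} requires {expected} "
                f"J value(s), got {len(self.j_values)}"
            )


@dataclass(frozen=True)
class MetaboliteLibrary:
    """Ordered collection of :class:`MetabolitePeak` entries."""

    peaks: tuple[MetabolitePeak, ...]
    metabolite_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.metabolite_names:
            seen: list[str] = []
            for p in self.peaks:
                if p.metabolite_name not in seen:
                    seen.append(p.metabolite_name)
            object.__setattr__(self, "metabolite_names", tuple(seen))
        names = set(self.metabolite_names)
        for p in self.peaks:
            if p.metabolite_name not in names:
                raise ValueError(
                    f"peak metabolite {p.metabolite_name!r} not in "
                    "metabolite_names"
                )

    def peaks_of(self, name: str) -> tuple[MetabolitePeak, ...]:
        """All peaks of one metabolite, in library order."""
        return tuple(p for p in self.peaks if p.metabolite_name == name)

    def __len__(self) -> int:
        return len(self.metabolite_names)


def _mid(a: float, b: float) -> float:
    return round((a + b) / 2.0, 4)


# (name, shift or (lo, hi) range, multiplicity, J values, assignment)
_PEAK_TABLE: tuple = (
    ("2-hydroxyisobutyrate", 1.34, "s", (), "H-3, H-4"),
    ("2-oxoglutarate", 2.44, "t", (6.92,), "H-5"),
    ("2-oxoglutarate", 2.99, "t", (6.92,), "H-4"),
    ("acetate", 1.91, "s", (), "H-2"),
    ("acetoacetate", 2.28, "s", (), "H-4"),
    ("alanine", 1.47, "d", (7.19,), "H-3"),
    ("alanine", 3.78, "q", (7.19,), "H-2"),
    ("asparagine", (2.82, 2.88), "m", (), "H-2"),
    ("asparagine", (2.90, 2.98), "m", (), "H-2"),
    ("asparagine", 4.01, "q", (4.26,), "H-3"),
    ("aspartate", 2.62, "dd", (8.7, 14.43), "H-2"),
    ("aspartate", 2.79, "dd", (3.78, 13.68), "H-2"),
    ("aspartate", 3.91, "dd", (3.75, 4.92), "H-3"),
    ("choline", 3.20, "s", (), "H-3, H-4, H-5"),
    ("choline", (3.48, 3.53), "m", (), "H-2"),
    ("choline", (4.03, 4.09), "m", (), "H-1"),
    ("citrate", 2.54, "d", (15.36,), "2Ha, 4Ha"),
    ("citrate", 2.68, "d", (15.36,), "2Hb, 4Hb"),
    ("formate", 8.46, "s", (), "H-1"),
    ("fumarate", 6.52, "s", (), "H-2, H-3"),
    ("galactarate", 3.94, "s", (), "H-3, H-4"),
    ("galactarate", 4.26, "s", (), "H-2, H-5"),
    ("glucose", 3.22, "dd", (1.44, 7.95), "H-2"),
    ("glucose", (3.38, 3.43), "m", (), "H-4"),
    ("glucose", (3.48, 3.54), "m", (), "H-5"),
    ("glucose", 3.52, "dd", (3.7, 9.82), "H-2"),
    ("glucose", (3.72, 3.78), "m", (), "H-3, H-6"),
    ("glucose", (3.80, 3.85), "m", (), "H-5, H-6"),
    ("glucose", 4.62, "d", (7.92,), "H-1"),
    ("glucose", 5.22, "d", (3.72,), "H-1"),
    ("glutamate", (2.00, 2.08), "m", (), "H-3"),
    ("glutamate", (2.10, 2.18), "m", (), "H-3"),
    ("glutamate", (2.28, 2.40), "m", (), "H-4"),
    ("glutamate", 3.75, "dd", (4.8, 2.4), "H-2"),
    ("hypoxanthine", 8.17, "s", (), "H-2"),
    ("hypoxanthine", 8.20, "s", (), "H-8"),
    ("isoleucine", 0.93, "t", (7.15,), "H-5"),
    ("isoleucine", 1.00, "d", (7.15,), "CH3"),
    ("isoleucine", (1.41, 1.49), "m", (), "H-4"),
    ("isoleucine", (1.92, 2.01), "m", (), "H-3"),
    ("isoleucine", 3.66, "d", (4.08,), "H-2"),
    ("leucine", 0.94, "t", (6.06,), "H-5, CH3"),
    ("leucine", (1.64, 1.78), "m", (), "H-3, H-4"),
    ("leucine", (3.69, 3.76), "m", (), "H-2"),
    ("malonate", 3.13, "s", (), "H-2"),
    ("oxypurinol", 8.27, "s", (), "H-7"),
    ("raffinose/stachyose", 3.52, "t", (4.5,), "H-4'"),
    ("raffinose/stachyose", 3.69, "br_s", (), "H-6"),
    ("raffinose/stachyose", 3.95, "t", (6.36,), "H-5''"),
    ("raffinose/stachyose", 4.95, "dd", (2.7, 4.1), "H-1''"),
    ("raffinose/stachyose", 5.41, "d", (4.5,), "H-1"),
    ("succinate", 2.42, "s", (), "H-2, H-3"),
    ("sucrose", 3.55, "dd", (3.84, 6.12), "H-1'"),
    ("sucrose", 3.66, "s", (), "H-1"),
    ("sucrose", 3.75, "t", (9.05,), "H-3"),
    ("sucrose", (3.76, 3.84), "m", (), "H-6"),
    ("sucrose", 4.04, "t", (9.05,), "H-4'"),
    ("sucrose", 5.39, "d", (3.84,), "H-1"),
    ("tartarate", 4.34, "s", (), "H-2, H-3"),
    ("tryptophan", (7.20, 7.24), "m", (), "H-8"),
    ("tryptophan", (7.18, 7.28), "m", (), "H-9"),
    ("tryptophan", 7.32, "s", (), "H-2"),
    ("tryptophan", 7.71, "d", (7.92,), "H-7"),
    ("valine", 0.98, "d", (7.02,), "CH3"),
    ("valine", 1.05, "d", (7.14,), "H-4"),
    ("valine", (2.20, 2.32), "m", (), "H-3"),
    ("valine", 3.61, "d", (4.33,), "H-2"),
)


def build_metabolite_library() -> MetaboliteLibrary:
    """Build the full 25-metabolite soybean assignment library.

    Shift ranges become their midpoints; compound entries separated by a
    slash ("raffinose/stachyose") are one metabolite.

    Returns
    -------
    MetaboliteLibrary
        Library with 25 metabolite names and one peak per assignment row.
    """
    peaks = []
    for name, shift, mult, js, label in _PEAK_TABLE:
        if isinstance(shift, tuple):
            shift = _mid(*shift)
        peaks.append(
            MetabolitePeak(
                metabolite_name=name,
                center_shift=float(shift),
                multiplicity=mult,
                j_values=tuple(float(j) for j in js),
                assignment_label=label,
            )
        )
    return MetaboliteLibrary(peaks=tuple(peaks))
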