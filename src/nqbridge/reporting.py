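"""Series-level summaries: compound records and rank correlations.

The descriptor analyses converge on a per-compound record (HOMA of the
quinoid and benzene rings, PT barrier, second-minimum energy, O–H
stretching wavenumber).  Across a substitution series those quantities
move together — lower quinoid-ring aromaticity goes with a higher
barrier, a higher second minimum and a higher harmonic O–H wavenumber —
so the headline statistic is the tie-corrected Spearman rank correlation
over pairwise-complete records: the claims are monotone-association
claims, not linearity claims.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .aromaticity import HomaParameters, homa, read_bond_table
from .datasets import ring_bond_labels
from .ptprofile import analyze_profile, read_profile
from .spectra import DEFAULT_OH_WINDOW, BandSummary, PowerSpectrum, barycenter

__all__ = [
    "CompoundRecord",
    "SeriesReport",
    "build_report",
    "load_series",
    "LABEL_RE",
]

#: compound-label grammar: group digit, pattern letter, optional mirror tag
LABEL_RE = re.compile(r"^([123])([a-g])(\(M\))?$")

#: quantities entering the correlation table
_CORR_FIELDS = ("homa_quinoid", "E_barrier", "E_min2", "nu_OH")


@dataclass
class CompoundRecord:
    """Per-compound descriptor values; missing analyses stay None."""

    compound: str
    substitution: dict[str, str] = field(default_factory=dict)  # R1..R4 -> H/Br
    homa_quinoid: float | None = None
    homa_aromatic: float | None = None
    E_barrier: float | None = None
    E_min2: float | None = None
    nu_OH: float | None = None
    possession: tuple[float, float] | None = None  # donor fractions

    def __post_init__(self) -> None:
        if not LABEL_RE.match(self.compound):
            raise ValueError(
                f"label {self.compound!r} does not follow the series grammar "
                "(group digit 1-3 + letter a-g + optional '(M)')"
            )

    @property
    def group(self) -> int:
        return int(self.compound[0])


@dataclass
class SeriesReport:
    records: list[CompoundRecord]
    correlations: pd.DataFrame  # Spearman rho, NaN where undefined
    table: pd.DataFrame


def _spearman(x: list[float], y: list[float]) -> float:
    if len(x) < 3:
        return float("nan")
    if len(set(x)) == 1 or len(set(y)) == 1:
        return float("nan")  # zero variance: rank correlation undefined
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def build_report(records: list[CompoundRecord]) -> SeriesReport:
    """Tabulate descriptor values and their pairwise rank correlations.

    Correlations use pairwise-complete observations; any pair with fewer
    than 3 usable records is flagged NaN.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a series report")
    table = pd.DataFrame(
        [
            {
                "compound": r.compound,
                "homa_quinoid": r.homa_quinoid,
                "homa_aromatic": r.homa_aromatic,
                "E_barrier": r.E_barrier,
                "E_min2": r.E_min2,
                "nu_OH": r.nu_OH,
            }
            for r in sorted(records, key=lambda r: r.compound)
        ]
    )
    corr = pd.DataFrame(
        np.eye(len(_CORR_FIELDS)), index=_CORR_FIELDS, columns=_CORR_FIELDS
    )
    for i, a in enumerate(_CORR_FIELDS):
        for b in _CORR_FIELDS[i + 1 :]:
            sub = table[[a, b]].dropna()
            rho = _spearman(sub[a].tolist(), sub[b].tolist())
            corr.loc[a, b] = corr.loc[b, a] = rho
    return SeriesReport(records=list(records), correlations=corr, table=table)


def load_series(
    directory: str | Path, config: str | Path | None = None
) -> list[CompoundRecord]:
    """Build compound records from a directory of per-compound files.

    Recognized files, all optional per compound label ``L``:

    * ``L_bonds.tsv``   — bond-length table (one column per variant; the
      first column is used) → quinoid/benzene-ring HOMA
    * ``L_profile.tsv`` — two-column PT scan (kcal/mol unless the config
      sets ``profile_units: hartree``) → barrier + second minimum
    * ``L_spectrum.tsv``— two-column (wavenumber, intensity) spectrum →
      band barycenter over the configured window

    Labels that do not follow the series grammar are skipped with a
    warning.  The optional YAML config may set ``ring_I``/``ring_II``
    bond labels, ``profile_units`` and ``nu_window``.
    """
    directory = Path(directory)
    cfg: dict = {}
    if config is not None:
        cfg = yaml.safe_load(Path(config).read_text()) or {}
    rings = ring_bond_labels()
    ring_i = cfg.get("ring_I", rings["ring_I"])
    ring_ii = cfg.get("ring_II", rings["ring_II"])
    units = cfg.get("profile_units", "kcal")
    window = tuple(cfg.get("nu_window", DEFAULT_OH_WINDOW))

    labels = sorted(
        {p.name.split("_")[0] for p in directory.glob("*_*.tsv")}
    )
    records: list[CompoundRecord] = []
    for label in labels:
        if not LABEL_RE.match(label):
            warnings.warn(f"skipping {label!r}: not a series compound label")
            continue
        rec = CompoundRecord(compound=label)
        bonds = directory / f"{label}_bonds.tsv"
        if bonds.exists():
            sets = read_bond_table(bonds)
            first = next(iter(sets.values()))
            try:
                rec.homa_quinoid = homa(first.subset(ring_i))
            except KeyError:
                pass
            try:
                rec.homa_aromatic = homa(first.subset(ring_ii))
            except KeyError:
                pass
        profile = directory / f"{label}_profile.tsv"
        if profile.exists():
            analysis = analyze_profile(read_profile(profile, units=units))
            rec.E_barrier = analysis.E_barrier
            rec.E_min2 = analysis.E_min2
        spectrum = directory / f"{label}_spectrum.tsv"
        if spectrum.exists():
            arr = np.loadtxt(spectrum)
            spec = PowerSpectrum(
                wavenumber=arr[:, 0],
                intensity=arr[:, 1],
                resolution=float(arr[1, 0] - arr[0, 0]),
            )
            rec.nu_OH = barycenter(spec, window).barycenter
        records.append(rec)
    return records
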