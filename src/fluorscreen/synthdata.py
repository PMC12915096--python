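"""Synthetic fluorophore libraries with planted structure–property rules.

Molecules are donor–π-bridge–acceptor dyes assembled from a fixed, validated
template set: a donor-substituted benzene, a polyene bridge of ``L`` vinylene
units, and an acceptor-substituted benzene, optionally decorated with small
ring substituents that diversify structures without touching the planted
photophysics.  The planted rules mimic textbook trends — bathochromic shift
with conjugation length and donor/acceptor strength, solvatochromic red shift
with solvent polarity, quantum yield falling with rotatable-bond count:

    λ_abs  = 300 + 25·L + 35·D + 35·A + 10·P  (nm)
    λ_em   = λ_abs + 40 + 8·P                 (nm)
    log ε  = 4.0 + 0.1·L
    Φ      = clamp01(logistic(1.5 − 0.5·R + 0.3·L))
    τ      = 1 + 4·Φ                          (ns)
    FWHM   = 40 + 6·R                         (nm, both bands)

with D/A ∈ {0, 0.5, 1} donor/acceptor strengths, R the rotatable-bond count,
P ∈ [0, 1] a solvent polarity index, plus Gaussian measurement noise.  The
binary fluorescence label is defined on the *intrinsic* (solvent-free, P = 0)
values: a molecule is labeled fluorescent under a query window iff both
|λ_abs − abs_query| and |λ_em − em_query| are within the half width and
Φ ≥ 0.05.  All constants are generator knobs with plausible visible-range
magnitudes, not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .curation import FLUORESCENT, NON_FLUORESCENT
from .errors import DataError
from .photophysics import AssaySeries, _hill, _one_site

# donor prefixes (strength D) and acceptor branch groups (strength A);
# the 3x3 grid gives the >= 6 donor-bridge-acceptor templates
DONORS = (("", 0.0), ("CO", 0.5), ("CN(C)", 1.0))
ACCEPTORS = (("", 0.0), ("C#N", 0.5), ("[N+](=O)[O-]", 1.0))
DECORATIONS = ("", "C", "F", "Cl", "OC", "CC", "C(C)C", "Br", "CCC", "OCC")

DEFAULT_SOLVENT_PALETTE = {
    "O": 1.0,            # water
    "CO": 0.76,          # methanol
    "CC#N": 0.46,        # acetonitrile
    "CS(C)=O": 0.44,     # dimethyl sulfoxide
    "Cc1ccccc1": 0.10,   # toluene
}

DEFAULT_NOISE_SD = {
    "abs_wavelength": 3.0,
    "em_wavelength": 3.0,
    "abs_fwhm": 2.0,
    "em_fwhm": 2.0,
    "log10_eps": 0.05,
    "plqy": 0.02,
    "lifetime": 0.2,
}


@dataclass
class PlantedRules:
    """Coefficients of the planted structure–property rules."""

    abs_base: float = 300.0
    abs_per_bridge: float = 25.0
    abs_per_donor: float = 35.0
    abs_per_acceptor: float = 35.0
    abs_per_polarity: float = 10.0
    stokes_shift: float = 40.0
    em_per_polarity: float = 8.0
    logeps_base: float = 4.0
    logeps_per_bridge: float = 0.1
    plqy_intercept: float = 1.5
    plqy_per_rotor: float = -0.5
    plqy_per_bridge: float = 0.3
    lifetime_base: float = 1.0
    lifetime_per_plqy: float = 4.0
    fwhm_base: float = 40.0
    fwhm_per_rotor: float = 6.0
    min_plqy_for_label: float = 0.05


@dataclass
class GeneratorSpec:
    n: int = 4000
    seed: int = 1
    bridge_length_range: tuple = (0, 5)
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    label_window: tuple = (390.0, 435.0, 55.0)  # (abs_query, em_query, half width)
    inconsistency_rate: float = 0.05
    solvent_palette: dict = field(default_factory=lambda: dict(DEFAULT_SOLVENT_PALETTE))
    solvents_per_molecule: int = 2
    rules: PlantedRules = field(default_factory=PlantedRules)

    def __post_init__(self):
        if not 0.0 <= self.inconsistency_rate <= 1.0:
            raise DataError("inconsistency_rate must lie in [0, 1]")
        lo, hi = self.bridge_length_range
        if lo < 0 or hi < lo:
            raise DataError("invalid bridge_length_range")


def build_dye_smiles(d_prefix: str, dec1: str, L: int, a_group: str, dec2: str) -> str:
    """Assemble one donor–bridge–acceptor SMILES from template parts."""
    bridge = "C=C" * L
    acc = f"({a_group})" if a_group else ""
    return f"{d_prefix}c1ccc({bridge}c2ccc{acc}cc2{dec2})cc1{dec1}"


def template_space(bridge_length_range=(0, 5)):
    """All distinct (donor, decoration1, L, acceptor, decoration2) combos."""
    lo, hi = bridge_length_range
    combos = []
    for d_prefix, D in DONORS:
        for a_group, A in ACCEPTORS:
            for L in range(lo, hi + 1):
                for dec1 in DECORATIONS:
                    for dec2 in DECORATIONS:
                        combos.append((d_prefix, D, a_group, A, L, dec1, dec2))
    return combos


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def intrinsic_properties(L: int, D: float, A: float, R: int, rules: PlantedRules) -> dict:
    """Noise-free property values at polarity P = 0."""
    lam_abs = rules.abs_base + rules.abs_per_bridge * L + rules.abs_per_donor * D \
        + rules.abs_per_acceptor * A
    plqy = float(np.clip(_logistic(
        rules.plqy_intercept + rules.plqy_per_rotor * R + rules.plqy_per_bridge * L
    ), 0.0, 1.0))
    fwhm = rules.fwhm_base + rules.fwhm_per_rotor * R
    return {
        "abs_wavelength": lam_abs,
        "em_wavelength": lam_abs + rules.stokes_shift,
        "log10_eps": rules.logeps_base + rules.logeps_per_bridge * L,
        "plqy": plqy,
        "lifetime": rules.lifetime_base + rules.lifetime_per_plqy * plqy,
        "abs_fwhm": fwhm,
        "em_fwhm": fwhm,
    }


def solvent_shift(prop: str, polarity: float, rules: PlantedRules) -> float:
    if prop == "abs_wavelength":
        return rules.abs_per_polarity * polarity
    if prop == "em_wavelength":
        return (rules.abs_per_polarity + rules.em_per_polarity) * polarity
    return 0.0


def true_label(intrinsic: dict, window: tuple, rules: PlantedRules) -> int:
    abs_q, em_q, hw = window
    return int(
        abs(intrinsic["abs_wavelength"] - abs_q) <= hw
        and abs(intrinsic["em_wavelength"] - em_q) <= hw
        and intrinsic["plqy"] >= rules.min_plqy_for_label
    )


def generate_library(spec: GeneratorSpec):
    """Generate a synthetic library.

    Returns ``(records, truth)``: ``records`` is a long-format table
    compatible with :func:`fluorscreen.curation.records_from_frame` (one
    label row per molecule plus per-solvent measurement rows), ``truth``
    holds one row per molecule with the planted descriptors, intrinsic
    property values and the true label.  Distinct structures are sampled
    without replacement, so the library never repeats a molecule.
    """
    rng = np.random.default_rng(spec.seed)
    space = template_space(spec.bridge_length_range)
    if spec.n > len(space):
        raise DataError(
            f"requested {spec.n} molecules but the template space has only "
            f"{len(space)} distinct structures"
        )
    picks = rng.choice(len(space), size=spec.n, replace=False)

    abs_q, em_q, hw = spec.label_window
    solvents = sorted(spec.solvent_palette)
    truth_rows, record_rows = [], []
    n_corrupt = 0
    for idx in picks:
        d_prefix, D, a_group, A, L, dec1, dec2 = space[idx]
        smiles = build_dye_smiles(d_prefix, dec1, L, a_group, dec2)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # templates are pre-validated; this is a hard bug
            raise DataError(f"generator emitted unparsable SMILES {smiles!r}")
        R = int(Descriptors.NumRotatableBonds(mol))
        intrinsic = intrinsic_properties(L, D, A, R, spec.rules)
        label = true_label(intrinsic, spec.label_window, spec.rules)
        truth_rows.append(
            {"smiles": smiles, "L": L, "D": D, "A": A, "R": R, "label": label,
             **intrinsic}
        )
        record_rows.append(
            {"smiles": smiles, "source": "synthetic", "score": None,
             "label": FLUORESCENT if label else NON_FLUORESCENT,
             "abs_query": abs_q, "em_query": em_q,
             "property": None, "value": None, "solvent_smiles": None}
        )
        k = min(spec.solvents_per_molecule, len(solvents))
        chosen = rng.choice(len(solvents), size=k, replace=False)
        corrupt = rng.random() < spec.inconsistency_rate
        for si in chosen:
            solvent = solvents[si]
            P = spec.solvent_palette[solvent]
            for prop, base in intrinsic.items():
                value = base + solvent_shift(prop, P, spec.rules)
                sd = spec.noise_sd.get(prop, 0.0)
                if sd > 0:
                    value += rng.normal(0.0, sd)
                if prop == "plqy":
                    value = float(np.clip(value, 0.0, 1.0))
                record_rows.append(
                    {"smiles": smiles, "source": "synthetic", "score": None,
                     "label": None, "abs_query": None, "em_query": None,
                     "property": prop, "value": float(value),
                     "solvent_smiles": solvent}
                )
        if corrupt:
            # an extra replicate offset well beyond the curation tolerance
            solvent = solvents[int(chosen[0])]
            P = spec.solvent_palette[solvent]
            base = intrinsic["em_wavelength"] + solvent_shift("em_wavelength", P, spec.rules)
            record_rows.append(
                {"smiles": smiles, "source": "synthetic", "score": None,
                 "label": None, "abs_query": None, "em_query": None,
                 "property": "em_wavelength", "value": float(base + 40.0),
                 "solvent_smiles": solvent}
            )
            n_corrupt += 1

    records = pd.DataFrame(record_rows)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["n_corrupted"] = n_corrupt
    truth.attrs["spec"] = asdict(spec)
    return records, truth


def generate_assay_curves(kind: str, params: dict, grid, noise_sd: float = 0.0,
                          seed: int = 0) -> AssaySeries:
    """Evaluate a closed-form assay model on a grid plus seeded noise.

    ``kind``: ``fh`` (Förster–Hoffmann, params C and x), ``kd`` (one-site
    binding: F0, Bmax, Kd) or ``hill`` (adds h).
    """
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    if kind == "fh":
        intensity = 10.0 ** (params["C"] + params["x"] * np.log10(grid))
    elif kind == "kd":
        intensity = _one_site(grid, params["F0"], params["Bmax"], params["Kd"])
    elif kind == "hill":
        intensity = _hill(grid, params["F0"], params["Bmax"], params["Kd"], params["h"])
    else:
        raise DataError(f"unknown assay kind {kind!r}")
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.shape)
    return AssaySeries(grid, intensity)
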