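"""Two-step screening pipeline and chemical-space characterization.

Step 1 scores every library molecule for fluorescence activity under a
wavelength query pair — retrieving stored experimental scores for molecules
already present in the training cache (zero network calls for those) and
predicting the rest.  Molecules scoring below the threshold are excluded.
Step 2 fills in the seven photophysical properties for the survivors, again
retrieving cached experimental values where available.

Hits are characterized by Bemis–Murcko scaffolds, ECFP4 fingerprints
(radius 2, 2048 bits) and a t-SNE projection of the fingerprint space.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.manifold import TSNE

from .curation import PROPERTIES, canonicalize
from .errors import DataError, DomainError, InvalidStructureError

logger = logging.getLogger(__name__)

RETRIEVED = "retrieved"
PREDICTED = "predicted"


@dataclass
class ScreeningRecord:
    canonical_smiles: str
    target_annotation: str | None
    provenance: str                     # retrieved | predicted (step-1 score)
    activity_score: float
    passed_l1: bool
    predicted_properties: dict = field(default_factory=dict)


def l1_cache_key(canonical_smiles: str, wavelength_pair) -> tuple:
    return (canonical_smiles, float(wavelength_pair.abs_nm), float(wavelength_pair.em_nm))


def l2_cache_key(canonical_smiles: str, solvent_smiles: str, prop: str) -> tuple:
    return (canonical_smiles, solvent_smiles, prop)


def build_l1_cache(samples, wavelength_pair) -> dict:
    """Retrieval cache mapping (smiles, abs, em) → stored experimental label."""
    return {
        l1_cache_key(s.smiles, wavelength_pair): float(s.target) for s in samples
    }


def build_l2_cache(samples, prop: str) -> dict:
    return {l2_cache_key(s.smiles, s.condition, prop): float(s.target) for s in samples}


def two_step_screen(library, l1_model, l2_models, wavelength_pair,
                    solvent_smiles, threshold: float):
    """Screen a library; returns ScreeningRecords sorted by score descending.

    ``library`` is an iterable of SMILES or (SMILES, target annotation)
    pairs.  ``l1_model`` must expose ``predict_activity_scores`` and a
    ``cache`` dict; each value of ``l2_models`` (property → model) must
    expose ``predict_property_values`` and ``cache``.  Scores below
    ``threshold`` drop out before step 2; ties in the final ranking break by
    lexicographic canonical SMILES.
    """
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold {threshold} outside [0, 1]")

    entries = []
    seen = set()
    for item in library:
        smiles, target = item if isinstance(item, (tuple, list)) else (item, None)
        try:
            can = canonicalize(smiles)
        except InvalidStructureError:
            logger.warning("skipping invalid library SMILES: %r", smiles)
            continue
        if can in seen:
            continue
        seen.add(can)
        entries.append((can, target))

    # step 1: retrieve where cached, predict the rest in one batch
    records = []
    misses = []
    for can, target in entries:
        key = l1_cache_key(can, wavelength_pair)
        if key in l1_model.cache:
            records.append(
                ScreeningRecord(can, target, RETRIEVED,
                                float(l1_model.cache[key]), False)
            )
        else:
            records.append(ScreeningRecord(can, target, PREDICTED, np.nan, False))
            misses.append((len(records) - 1, can))
    if misses:
        scores = l1_model.predict_activity_scores(
            [s for _, s in misses], wavelength_pair
        )
        for (idx, _), sc in zip(misses, scores):
            records[idx].activity_score = float(sc)

    for rec in records:
        rec.passed_l1 = rec.activity_score >= threshold

    # step 2: properties for survivors only
    survivors = [r for r in records if r.passed_l1]
    solvent_can = canonicalize(solvent_smiles)
    for prop, model in l2_models.items():
        misses = []
        for rec in survivors:
            key = l2_cache_key(rec.canonical_smiles, solvent_can, prop)
            if key in model.cache:
                rec.predicted_properties[prop] = float(model.cache[key])
            else:
                misses.append(rec)
        if misses:
            values = model.predict_property_values(
                [r.canonical_smiles for r in misses], solvent_smiles
            )
            for rec, v in zip(misses, values):
                rec.predicted_properties[prop] = float(v)

    records.sort(key=lambda r: (-r.activity_score, r.canonical_smiles))
    return records


def screening_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "smiles": r.canonical_smiles,
            "target": r.target_annotation,
            "provenance": r.provenance,
            "activity_score": r.activity_score,
            "passed_l1": r.passed_l1,
        }
        for prop in PROPERTIES:
            row[prop] = r.predicted_properties.get(prop)
        rows.append(row)
    return pd.DataFrame(rows)


# -------------------------------------------------------- chemical space

EMPTY_SCAFFOLD = "<acyclic>"


def murcko_scaffold(canonical_smiles: str) -> str:
    """Bemis–Murcko scaffold (ring systems + linkers, side chains pruned).

    Acyclic molecules yield the empty string.
    """
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise InvalidStructureError(canonical_smiles)
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def fingerprint(canonical_smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """ECFP-style circular fingerprint (radius 2 → ECFP4) as a 0/1 vector."""
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise InvalidStructureError(canonical_smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    inter = int(np.logical_and(fp_a, fp_b).sum())
    union = int(np.logical_or(fp_a, fp_b).sum())
    return inter / union if union else 1.0


def chemspace_embed(fingerprints, perplexity: float = 30.0, seed: int = 42) -> np.ndarray:
    """Project fingerprints to 2D with t-SNE; deterministic for a given seed."""
    X = np.asarray(fingerprints, dtype=np.float64)
    n = X.shape[0]
    if n < 5:
        raise DataError(f"need at least 5 molecules for an embedding, got {n}")
    if n <= 3 * perplexity:
        new = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for n={n}; reduced to {new:.1f}"
        )
        perplexity = new
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(X)
    if not np.isfinite(coords).all():
        raise DataError("t-SNE produced non-finite coordinates")
    return coords


def scaffold_frequencies(smiles_list, k: int = 20) -> pd.DataFrame:
    """Top-k scaffold table (count desc, ties lexicographic).

    Acyclic molecules are pooled into a dedicated ``<acyclic>`` bin.
    """
    if not len(smiles_list):
        raise DataError("empty SMILES list")
    counts = Counter()
    for s in smiles_list:
        scaf = murcko_scaffold(s)
        counts[scaf if scaf else EMPTY_SCAFFOLD] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(ranked, columns=["scaffold", "count"])


def plot_chemspace(coords, labels=None, path: str | None = None):
    """Scatter plot of the 2D embedding (optional artifact)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=8, alpha=0.7)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=8, alpha=0.7, label=str(lab))
        ax.legend(fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
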