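"""Attention-based interpretability statistics.

From the bidirectional attention matrices of a trained model, each drug
atom ranks the target residues it attends to, and each residue ranks the
drug atoms.  Two families of statistics summarize these rankings:

* residue side — the fraction of top-k residue picks (k in {5, 10, 20} by
  default, aggregated over atoms) that fall inside the binding pocket;
* atom side — the fraction of distinct heavy atoms covered by the top-k
  atom picks of the residues (k in {3, 5, 8} by default).

Ties are broken by ascending index, which makes every report deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network import AffinityModel

__all__ = [
    "InterpretReport",
    "DatasetInterpretReport",
    "top_k_rows",
    "pocket_hit_fraction",
    "interpret_complex",
    "interpret_dataset",
    "export_selections",
]

DEFAULT_K_RESIDUES = (5, 10, 20)
DEFAULT_K_ATOMS = (3, 5, 8)


def top_k_rows(score_matrix, k: int):
    """Per-row indices of the k largest entries.

    Ordered by descending score with ties broken by ascending index; when
    k exceeds the row length all indices are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    matrix = np.asarray(score_matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty score matrix")
    n_cols = matrix.shape[1]
    k_eff = min(k, n_cols)
    out = []
    for row in matrix:
        order = np.lexsort((np.arange(n_cols), -row))
        out.append([int(i) for i in order[:k_eff]])
    return out


def pocket_hit_fraction(top_indices, mask) -> float:
    """Fraction of (atom, residue) picks landing inside the pocket."""
    mask = np.asarray(mask, dtype=bool)
    total = hits = 0
    for picks in top_indices:
        for idx in picks:
            if not (0 <= idx < mask.shape[0]):
                raise IndexError(f"residue index {idx} out of range")
            hits += bool(mask[idx])
            total += 1
    if total == 0:
        raise ValueError("no picks to score")
    return hits / total


@dataclass
class InterpretReport:
    """Interpretability statistics for one complex."""

    complex_id: str
    n_residues: int
    n_atoms: int
    n_pocket: int
    residue_hit_fraction: dict = field(default_factory=dict)  # k -> fraction
    atom_coverage: dict = field(default_factory=dict)  # k -> fraction
    atoms_to_residues_topk: dict = field(default_factory=dict)  # k -> per-atom lists
    residues_to_atoms_topk: dict = field(default_factory=dict)  # k -> per-residue lists
    residue_pick_counts: dict = field(default_factory=dict)  # k -> (hits, picks)

    def as_dict(self) -> dict:
        return {
            "complex_id": self.complex_id,
            "n_residues": self.n_residues,
            "n_atoms": self.n_atoms,
            "n_pocket": self.n_pocket,
            "residue_hit_fraction": {str(k): v for k, v in self.residue_hit_fraction.items()},
            "atom_coverage": {str(k): v for k, v in self.atom_coverage.items()},
        }


def interpret_complex(
    sample,
    model: AffinityModel,
    k_res=DEFAULT_K_RESIDUES,
    k_atom=DEFAULT_K_ATOMS,
) -> InterpretReport:
    """Run the model with attention on one featurized sample and build the
    per-complex ranking statistics.

    The drug graph already excludes hydrogens, so atom-side coverage is the
    number of distinct picked heavy atoms over the heavy-atom count.
    """
    if sample.pocket_mask is None or not np.any(sample.pocket_mask):
        raise ValueError(f"{sample.complex_id}: missing or empty pocket mask")
    _, attention = model.forward(sample, want_attention=True)
    a2r = attention.atoms_to_residues
    r2a = attention.residues_to_atoms
    n_atoms, n_res = a2r.shape

    report = InterpretReport(
        complex_id=sample.complex_id,
        n_residues=n_res,
        n_atoms=n_atoms,
        n_pocket=int(np.sum(sample.pocket_mask)),
    )
    for k in k_res:
        picks = top_k_rows(a2r, k)
        report.atoms_to_residues_topk[k] = picks
        frac = pocket_hit_fraction(picks, sample.pocket_mask)
        report.residue_hit_fraction[k] = frac
        n_picks = sum(len(p) for p in picks)
        report.residue_pick_counts[k] = (int(round(frac * n_picks)), n_picks)
    for k in k_atom:
        picks = top_k_rows(r2a, k)
        report.residues_to_atoms_topk[k] = picks
        distinct = {i for row in picks for i in row}
        report.atom_coverage[k] = len(distinct) / n_atoms
    return report


@dataclass
class DatasetInterpretReport:
    """Aggregated statistics over many complexes.

    Residue-side fractions are reported both pooled over all picks and as
    the unweighted mean of per-complex fractions.
    """

    per_complex: list
    residue_hit_fraction_pooled: dict = field(default_factory=dict)
    residue_hit_fraction_mean: dict = field(default_factory=dict)
    atom_coverage_mean: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_complexes": len(self.per_complex),
            "residue_hit_fraction_pooled": {
                str(k): v for k, v in self.residue_hit_fraction_pooled.items()
            },
            "residue_hit_fraction_mean": {
                str(k): v for k, v in self.residue_hit_fraction_mean.items()
            },
            "atom_coverage_mean": {str(k): v for k, v in self.atom_coverage_mean.items()},
            "per_complex": [r.as_dict() for r in self.per_complex],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def interpret_dataset(
    samples, model: AffinityModel, k_res=DEFAULT_K_RESIDUES, k_atom=DEFAULT_K_ATOMS
) -> DatasetInterpretReport:
    reports = [interpret_complex(s, model, k_res=k_res, k_atom=k_atom) for s in samples]
    out = DatasetInterpretReport(per_complex=reports)
    for k in k_res:
        hits = sum(r.residue_pick_counts[k][0] for r in reports)
        picks = sum(r.residue_pick_counts[k][1] for r in reports)
        out.residue_hit_fraction_pooled[k] = hits / picks
        out.residue_hit_fraction_mean[k] = float(
            np.mean([r.residue_hit_fraction[k] for r in reports])
        )
    for k in k_atom:
        out.atom_coverage_mean[k] = float(
            np.mean([r.atom_coverage[k] for r in reports])
        )
    return out


def export_selections(report: InterpretReport, sample, path, k: int) -> None:
    """Write plain-text residue/atom selection lists for external viewers."""
    lines = [f"# {report.complex_id}: top-{k} picks"]
    labels = sample.target_graph.vertex_labels or [
        str(i) for i in range(report.n_residues)
    ]
    picked_res = sorted({i for row in report.atoms_to_residues_topk.get(k, []) for i in row})
    lines.append("[residues]")
    lines.extend(labels[i] for i in picked_res)
    atom_labels = sample.drug_graph.vertex_labels or [
        str(i) for i in range(report.n_atoms)
    ]
    atom_rows = report.residues_to_atoms_topk.get(k)
    if atom_rows is None and report.residues_to_atoms_topk:
        nearest = min(report.residues_to_atoms_topk, key=lambda kk: abs(kk - k))
        atom_rows = report.residues_to_atoms_topk[nearest]
    picked_atoms = sorted({i for row in (atom_rows or []) for i in row})
    lines.append("[atoms]")
    lines.extend(atom_labels[i] for i in picked_atoms)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
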