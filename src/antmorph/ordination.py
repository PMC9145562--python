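"""Principal component analysis for visual comparison of uninfected,
infected, and reconstructed specimens.

PCA is fitted per species (the group structure of interest is within
species) on the correlation matrix by default — traits share micrometre
units but differ in magnitude by an order of magnitude, so each trait is
centred and divided by its SD before the eigendecomposition.  The first
two axes are retained for visualisation.  Reconstructed specimens are
*projected* into the space fitted on observed specimens, never refitted.

A deterministic sign convention (the largest-magnitude loading of each
component is positive) makes results reproducible across runs and
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .morphdata import SpecimenTable
from .reconstruct import ReconstructedTable

__all__ = ["PcaResult", "fit_pca", "project", "per_species_ordination",
           "plot_ordination"]


@dataclass(frozen=True)
class PcaResult:
    """Fitted PCA: loadings, scores of the fitted data, explained
    variance, and the centring/scaling needed to project new data."""

    loadings: np.ndarray            # (n_traits, n_axes)
    scores: np.ndarray              # (n_specimens, n_axes)
    explained_variance_ratio: np.ndarray  # all axes, non-increasing
    center: np.ndarray
    scale: np.ndarray               # ones when scale=False
    traits: tuple[str, ...]
    n_axes: int


def _trait_matrix(table) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(table, SpecimenTable):
        return table.trait_matrix(), tuple(table.registry)
    arr = np.asarray(table, dtype=float)
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def fit_pca(table, n_axes: int = 2, scale: bool = True) -> PcaResult:
    """Eigendecomposition of the (optionally correlation-) covariance
    matrix via SVD of the centred data.

    Requires at least 3 specimens and at least ``n_axes`` traits.
    Constant traits are tolerated under ``scale=True`` by leaving them
    unscaled (they carry no variance either way).
    """
    X, traits = _trait_matrix(table)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    if p < n_axes:
        raise ValueError(f"cannot retain {n_axes} axes from {p} traits")
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scl = np.where(sd > 0, sd, 1.0) if scale else np.ones(p)
    Z = (X - center) / scl
    _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each axis positive
    V = Vt.T
    for j in range(V.shape[1]):
        lead = np.argmax(np.abs(V[:, j]))
        if V[lead, j] < 0:
            V[:, j] = -V[:, j]
    var = svals ** 2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    loadings = V[:, :n_axes]
    return PcaResult(
        loadings=loadings,
        scores=Z @ loadings,
        explained_variance_ratio=ratio,
        center=center,
        scale=scl,
        traits=traits,
        n_axes=n_axes,
    )


def project(result: PcaResult, table) -> np.ndarray:
    """Map new specimens into a fitted PCA space using the stored
    centring and scaling."""
    X, traits = _trait_matrix(table)
    if isinstance(table, SpecimenTable) and traits != result.traits:
        raise ValueError("trait sets of the PCA fit and the projection "
                         "input differ")
    if X.shape[1] != len(result.traits):
        raise ValueError(
            f"expected {len(result.traits)} trait columns, got {X.shape[1]}"
        )
    return (X - result.center) / result.scale @ result.loadings


def per_species_ordination(
    table: SpecimenTable,
    recon: ReconstructedTable | None = None,
    n_axes: int = 2,
    scale: bool = True,
) -> dict[str, tuple[PcaResult, pd.DataFrame]]:
    """Fit a PCA per species on the observed specimens and project any
    reconstructed specimens into it.

    Returns, per species, the fitted :class:`PcaResult` and a score
    frame with columns pc1..pcN plus ``group`` in {uninfected, infected,
    reconstructed}.
    """
    out: dict[str, tuple[PcaResult, pd.DataFrame]] = {}
    for species in table.species_levels:
        sub = table.subset(table.data["species"] == species)
        res = fit_pca(sub, n_axes=n_axes, scale=scale)
        cols = [f"pc{i + 1}" for i in range(n_axes)]
        frame = pd.DataFrame(res.scores, columns=cols)
        frame["specimen_id"] = sub.data["specimen_id"].to_numpy()
        frame["group"] = np.where(
            sub.data["infected"].to_numpy(), "infected", "uninfected"
        )
        if recon is not None:
            rsub = recon.data[
                (recon.data["species"] == species) & recon.data["reconstructed"]
            ]
            if len(rsub):
                rscores = project(res, rsub[list(table.registry)].to_numpy())
                rframe = pd.DataFrame(rscores, columns=cols)
                rframe["specimen_id"] = rsub["specimen_id"].to_numpy()
                rframe["group"] = "reconstructed"
                frame = pd.concat([frame, rframe], ignore_index=True)
        out[species] = (res, frame)
    return out


_GROUP_STYLE = {
    "uninfected": dict(marker="o", facecolor="C0", edgecolor="C0",
                       label="uninfected"),
    "infected": dict(marker="^", facecolor="C3", edgecolor="C3",
                     label="infected"),
    "reconstructed": dict(marker="^", facecolor="none", edgecolor="C2",
                          label="reconstructed"),
}


def plot_ordination(
    ordinations: dict[str, tuple[PcaResult, pd.DataFrame]],
    outdir,
    prefix: str = "pca",
) -> list[str]:
    """One scatter figure per species: circles for uninfected, filled
    triangles for infected, empty triangles for reconstructed.  Groups
    absent from a species are omitted from the legend.  Returns the
    written file paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for species, (res, frame) in ordinations.items():
        fig, ax = plt.subplots(figsize=(5, 4.5))
        for group, style in _GROUP_STYLE.items():
            sel = frame[frame["group"] == group]
            if sel.empty:
                continue
            ax.scatter(
                sel["pc1"], sel["pc2"], s=45,
                marker=style["marker"], facecolors=style["facecolor"],
                edgecolors=style["edgecolor"], label=style["label"],
            )
        evr = res.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
        ax.set_title(species)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = outdir / f"{prefix}_{species}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(str(path))
    return paths
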