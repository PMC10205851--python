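"""Synthetic data with planted structure for every downstream stage.

The count generator emulates the statistical features the pipeline
assumes: negative-binomial counts with log-normal library sizes, a
disjoint elevated marker program per cell line plus a smaller nested
program per subcluster, a dead-cell subpopulation whose mitochondrial
fraction is drawn from a high mode (making percent.mito bimodal),
doublets as sums of two cells, and bimodal receptor genes (ESR1 / PGR /
ERBB2) with per-line positive fractions.  Gene symbols follow the human
conventions the pipeline keys on: "MT-" mitochondrial genes and
"RPL"/"RPS" ribosomal decoys.

The stemness-gradient generator rewrites expression over a PPI network's
genes so that a cell with planted stemness s interpolates between
uniform-diffuse coverage of the network (s=1) and concentration on one
designated pathway (s=0); the image generator paints disk-shaped cells
with bimodal FITC intensity.  Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from skimage.draw import disk as disk_pixels

from ._log import logger
from .ppi import PPINetwork, ppi_from_edges

MT_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB", "MT-ND3", "MT-ND4")
SENTINEL_MEAN = 10.0
SENTINEL_DISPERSION = 2.0
MARKER_DISPERSION = 5.0
BACKGROUND_DISPERSION = 2.0


@dataclass
class SimulationTruth:
    """Ground truth for a simulated dataset."""

    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    image_centers: np.ndarray | None = None  # (n, 2) as (x, y)
    image_radii: np.ndarray | None = None
    image_positive: np.ndarray | None = None
    params: dict = field(default_factory=dict)


# Default per-line receptor positive fractions: a HER2-overexpressing
# line, a hormone-receptor (Luminal-like) line and a triple-negative
# line, cycled when more lines are requested.
DEFAULT_RECEPTOR_PROFILES = (
    {"ESR1": 0.05, "PGR": 0.05, "ERBB2": 0.90},
    {"ESR1": 0.90, "PGR": 0.85, "ERBB2": 0.05},
    {"ESR1": 0.05, "PGR": 0.05, "ERBB2": 0.05},
)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion theta): var = mean + mean^2/theta."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    theta = np.asarray(dispersion, dtype=float)
    p = theta / (theta + mean)
    return rng.negative_binomial(np.broadcast_to(theta, mean.shape), p)


def simulate_counts(
    n_lines: int = 3,
    subclusters_per_line: int = 2,
    cells_per_subcluster: int = 60,
    n_genes: int = 500,
    seed: int = 0,
    dead_fraction: float = 0.08,
    doublet_fraction: float = 0.01,
    marker_effect: float = 8.0,
    sub_effect: float = 4.0,
    markers_per_line: int = 20,
    markers_per_subcluster: int = 10,
    marker_base_mean: float = 0.3,
    background_mean: float = 0.5,
    library_sigma: float = 0.3,
    live_mito: tuple[float, float] = (0.05, 0.012),
    dead_mito: tuple[float, float] = (0.20, 0.035),
    receptor_profiles: tuple[dict, ...] | None = None,
) -> tuple[ad.AnnData, SimulationTruth]:
    """Simulate a cell-line count matrix with planted structure.

    Each line gets ``markers_per_line`` disjoint program genes elevated
    ``marker_effect``-fold; each subcluster a smaller nested program.
    ``dead_fraction`` of cells get their mitochondrial fraction from the
    high mode; ``doublet_fraction`` are sums of two cells' counts.
    Receptor genes are two-component mixtures with per-line positive
    fractions (defaults plant a HER2+, a Luminal and a TNBC line).
    """
    if n_genes < 200:
        raise ValueError("n_genes must be >= 200")
    if min(n_lines, subclusters_per_line, cells_per_subcluster) < 1:
        raise ValueError("all counts must be >= 1")
    n_program = n_lines * (markers_per_line + subclusters_per_line * markers_per_subcluster)
    n_special = 3 + len(MT_GENES) + 20 + 5  # receptors + mito + ribo decoys + sentinels
    if n_program + n_special > n_genes:
        raise ValueError(
            f"requested programs need {n_program + n_special} genes but only {n_genes} available"
        )
    rng = np.random.default_rng(seed)
    if receptor_profiles is None:
        receptor_profiles = tuple(
            DEFAULT_RECEPTOR_PROFILES[l % len(DEFAULT_RECEPTOR_PROFILES)] for l in range(n_lines)
        )

    # ---- gene table -------------------------------------------------
    symbols: list[str] = ["ESR1", "PGR", "ERBB2"]
    program: list[str] = ["receptor"] * 3
    marker_of: list[str] = [""] * 3
    symbols += list(MT_GENES)
    program += ["mito"] * len(MT_GENES)
    marker_of += [""] * len(MT_GENES)
    for i in range(10):
        symbols += [f"RPL{i + 1}", f"RPS{i + 1}"]
        program += ["ribo", "ribo"]
        marker_of += ["", ""]
    for i in range(5):
        symbols.append(f"SENTINEL{i + 1}")
        program.append("sentinel")
        marker_of.append("")
    for l in range(n_lines):
        for j in range(markers_per_line):
            symbols.append(f"LINE{l}M{j + 1}")
            program.append("line_marker")
            marker_of.append(f"line{l}")
        for s in range(subclusters_per_line):
            for j in range(markers_per_subcluster):
                symbols.append(f"L{l}S{s}M{j + 1}")
                program.append("subcluster_marker")
                marker_of.append(f"line{l}/sub{s}")
    n_bg = n_genes - len(symbols)
    symbols += [f"GENE{i + 1}" for i in range(n_bg)]
    program += ["background"] * n_bg
    marker_of += [""] * n_bg
    genes = pd.DataFrame({"program": program, "marker_of": marker_of}, index=pd.Index(symbols, name="gene"))

    # ---- per-cell assignments --------------------------------------
    n_cells = n_lines * subclusters_per_line * cells_per_subcluster
    line_id = np.repeat([f"line{l}" for l in range(n_lines)], subclusters_per_line * cells_per_subcluster)
    sub_id = np.tile(np.repeat([f"sub{s}" for s in range(subclusters_per_line)], cells_per_subcluster), n_lines)
    is_dead = rng.random(n_cells) < dead_fraction
    lib = np.exp(rng.normal(0.0, library_sigma, n_cells))
    mito_frac = np.where(
        is_dead,
        rng.normal(dead_mito[0], dead_mito[1], n_cells),
        rng.normal(live_mito[0], live_mito[1], n_cells),
    )
    mito_frac = np.clip(mito_frac, 0.005, 0.6)

    # ---- expected means (cells x genes) ----------------------------
    base = np.empty(n_genes)
    disp = np.full(n_genes, BACKGROUND_DISPERSION)
    prog = genes["program"].to_numpy()
    base[prog == "background"] = rng.gamma(2.0, background_mean / 2.0, int((prog == "background").sum()))
    base[prog == "ribo"] = rng.gamma(2.0, 1.0, int((prog == "ribo").sum()))  # abundant decoys
    base[prog == "sentinel"] = SENTINEL_MEAN
    disp[prog == "sentinel"] = SENTINEL_DISPERSION
    base[prog == "line_marker"] = marker_base_mean
    base[prog == "subcluster_marker"] = marker_base_mean
    disp[np.isin(prog, ["line_marker", "subcluster_marker"])] = MARKER_DISPERSION
    base[prog == "mito"] = 0.0  # filled per cell below
    disp[prog == "mito"] = 50.0  # near-Poisson: keeps realized pct_mito close to the planted fraction
    base[prog == "receptor"] = 0.0

    M = np.tile(base, (n_cells, 1))
    for l in range(n_lines):
        rows = line_id == f"line{l}"
        cols = (genes["marker_of"] == f"line{l}").to_numpy()
        M[np.ix_(rows, cols)] *= marker_effect
        for s in range(subclusters_per_line):
            srows = rows & (sub_id == f"sub{s}")
            scols = (genes["marker_of"] == f"line{l}/sub{s}").to_numpy()
            M[np.ix_(srows, scols)] *= sub_effect

    # receptors: two-component mixture, positive fraction per line
    receptor_true = {r: np.zeros(n_cells, dtype=bool) for r in ("ESR1", "PGR", "ERBB2")}
    for l in range(n_lines):
        rows = np.flatnonzero(line_id == f"line{l}")
        for r, frac in receptor_profiles[l].items():
            pos = rows[rng.random(rows.size) < frac]
            receptor_true[r][pos] = True
    for r in ("ESR1", "PGR", "ERBB2"):
        j = symbols.index(r)
        M[:, j] = np.where(receptor_true[r], 15.0, 0.05)
        disp[j] = 10.0

    # library-size scaling for everything except calibration sentinels
    scale_cols = prog != "sentinel"
    M[:, scale_cols] *= lib[:, None]

    # mitochondrial means chosen per cell so the expected mito fraction
    # equals the planted mixture draw
    mito_cols = np.flatnonzero(prog == "mito")
    nonmito_sum = M.sum(axis=1)  # mito columns currently 0
    mito_total = mito_frac / (1.0 - mito_frac) * nonmito_sum
    share = rng.dirichlet(np.full(len(mito_cols), 20.0))
    M[:, mito_cols] = mito_total[:, None] * share[None, :]

    counts = _nb_sample(rng, M, disp[None, :])

    # doublets: add a random partner cell's counts
    is_doublet = np.zeros(n_cells, dtype=bool)
    n_doub = int(rng.binomial(n_cells, doublet_fraction))
    if n_doub:
        targets = rng.choice(n_cells, size=n_doub, replace=False)
        partners = rng.integers(0, n_cells, size=n_doub)
        counts[targets] += counts[partners]
        is_doublet[targets] = True

    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.float64)),
        obs=pd.DataFrame({"line_id": line_id, "subcluster_id": sub_id}, index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame({"gene_id": symbols, "program": program}, index=genes.index.copy()),
    )
    truth = SimulationTruth(
        cells=pd.DataFrame(
            {
                "line_id": line_id,
                "subcluster_id": sub_id,
                "is_dead": is_dead,
                "is_doublet": is_doublet,
                "mito_fraction": mito_frac,
                "stemness_level": np.nan,
                "ESR1_positive": receptor_true["ESR1"],
                "PGR_positive": receptor_true["PGR"],
                "ERBB2_positive": receptor_true["ERBB2"],
            },
            index=pd.Index(barcodes, name="barcode"),
        ),
        genes=genes,
        params={
            "seed": seed,
            "dead_fraction": dead_fraction,
            "doublet_fraction": doublet_fraction,
            "marker_effect": marker_effect,
            "sentinel_mean": SENTINEL_MEAN,
            "sentinel_dispersion": SENTINEL_DISPERSION,
            "expected_pct_mito": float(np.mean(mito_frac) * 100),
            "receptor_profiles": receptor_profiles,
        },
    )
    logger.info("stage=simulate_counts n_cells=%d n_genes=%d seed=%d", n_cells, n_genes, seed)
    return adata, truth


def simulate_ppi(
    n_nodes: int = 30,
    neighbors: int = 2,
    rewire_p: float = 0.1,
    seed: int = 0,
    prefix: str = "GENE",
    pathway_fraction: float = 0.2,
) -> tuple[PPINetwork, tuple[str, ...]]:
    """Small-world (Watts-Strogatz) PPI over ``prefix``-named genes.

    Returns the network and the designated "pathway": a contiguous,
    low-branching arc of the ring covering ``pathway_fraction`` of the
    nodes.  Concentrating expression there confines the expression-
    weighted random walk to a thin subgraph, which is what gives
    committed (low-stemness) cells their low signaling entropy; the
    near-homogeneous degrees of the ring keep diffuse expression close
    to the maximal-entropy walk.
    """
    import random as _random

    _random.seed(seed)
    for _ in range(50):
        g = igraph.Graph.Watts_Strogatz(1, n_nodes, neighbors, rewire_p)
        g.simplify()
        if g.is_connected():
            break
    else:
        raise RuntimeError("could not generate a connected network")
    names = tuple(f"{prefix}{i + 1}" for i in range(n_nodes))
    edges = [(names[e.source], names[e.target], 1.0) for e in g.es]
    net = ppi_from_edges(edges)
    k = max(3, int(round(pathway_fraction * n_nodes)))
    pathway = tuple(names[:k])
    return net, pathway


def simulate_stemness_gradient(
    adata: ad.AnnData,
    network: PPINetwork,
    truth: SimulationTruth,
    seed: int = 0,
    pathway: tuple[str, ...] | None = None,
    budget: float = 300.0,
    pathway_mass: float = 0.9,
) -> ad.AnnData:
    """Plant a stemness gradient over the network genes.

    Each cell receives a stemness level s ~ U(0,1) (written to the truth
    table).  Its expression over the network's genes is resampled as
    Poisson around budget * (s * uniform + (1-s) * concentrated), where
    the concentrated profile puts ``pathway_mass`` of the mass on the
    designated pathway.  Diffuse cells (s=1) therefore carry near-uniform
    coverage of the network and score high signaling entropy; committed
    cells (s=0) concentrate on one pathway and score low.
    """
    missing = [g for g in network.genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"network genes missing from matrix: {missing[:5]}...")
    rng = np.random.default_rng(seed)
    n_cells = adata.n_obs
    G = network.n_genes
    if pathway is None:
        degs = network.degrees()
        hub = int(np.argmax(degs))
        nbrs = network.adjacency[hub].nonzero()[1]
        pathway = tuple([network.genes[hub]] + [network.genes[j] for j in nbrs])
    pathway_set = set(pathway)
    in_path = np.array([g in pathway_set for g in network.genes])
    k = int(in_path.sum())
    uniform = np.full(G, 1.0 / G)
    conc = np.where(in_path, pathway_mass / k, (1.0 - pathway_mass) / max(G - k, 1))

    s = rng.uniform(0.0, 1.0, n_cells)
    means = s[:, None] * uniform[None, :] + (1 - s[:, None]) * conc[None, :]
    counts = rng.poisson(budget * means)

    X = sp.lil_matrix(adata.X.copy())
    cols = [adata.var_names.get_loc(g) for g in network.genes]
    X[:, cols] = counts
    adata = adata.copy()
    adata.X = X.tocsr()
    truth.cells["stemness_level"] = s
    truth.params["pathway"] = tuple(pathway)
    logger.info("stage=simulate_stemness_gradient n_cells=%d n_network_genes=%d", n_cells, G)
    return adata


def simulate_image(
    n_cells: int,
    width: int = 512,
    height: int = 512,
    radius_range: tuple[int, int] = (8, 14),
    positive_fraction: float = 0.45,
    intensity_modes: tuple[tuple[float, float], tuple[float, float]] = ((6000.0, 800.0), (20000.0, 2000.0)),
    noise_sd: float = 300.0,
    seed: int = 0,
    bf_background: float = 30000.0,
    bf_disk: float = 8000.0,
    max_tries_per_cell: int = 200,
) -> tuple[tuple[np.ndarray, np.ndarray], SimulationTruth]:
    """Paired brightfield/FITC 16-bit images of disk-shaped cells.

    Brightfield: dark disks on a bright background.  FITC: each disk's
    intensity drawn from the negative or positive mode according to its
    true class.  Centers are rejection-sampled to be non-overlapping;
    persistent placement failure raises a capacity error.
    """
    rng = np.random.default_rng(seed)
    r_lo, r_hi = radius_range
    if r_hi * 2 >= min(width, height):
        raise ValueError("disks do not fit in the frame")
    if n_cells * np.pi * r_hi**2 > 0.6 * width * height:
        raise ValueError("requested coverage exceeds 60% of the frame area")

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n_cells):
        placed = False
        for _try in range(max_tries_per_cell):
            r = rng.uniform(r_lo, r_hi)
            x = rng.uniform(r + 1, width - r - 1)
            y = rng.uniform(r + 1, height - r - 1)
            if all((x - cx) ** 2 + (y - cy) ** 2 > (r + cr + 3) ** 2 for (cx, cy), cr in zip(centers, radii)):
                centers.append((x, y))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place cell {len(centers) + 1} after {max_tries_per_cell} tries")

    positive = rng.random(n_cells) < positive_fraction

    bf = np.full((height, width), bf_background, dtype=float)
    fitc = np.full((height, width), 2000.0, dtype=float)
    for (x, y), r, pos in zip(centers, radii, positive):
        rr, cc = disk_pixels((y, x), r, shape=(height, width))
        bf[rr, cc] = bf_disk
        mode = intensity_modes[1] if pos else intensity_modes[0]
        fitc[rr, cc] = rng.normal(mode[0], mode[1])
    bf += rng.normal(0.0, noise_sd, bf.shape)
    fitc += rng.normal(0.0, noise_sd, fitc.shape)
    bf = np.clip(bf, 0, 65535).astype(np.uint16)
    fitc = np.clip(fitc, 0, 65535).astype(np.uint16)

    truth = SimulationTruth(
        image_centers=np.array(centers).reshape(-1, 2),
        image_radii=np.array(radii),
        image_positive=positive,
        params={"seed": seed, "positive_fraction": positive_fraction, "n_cells": n_cells},
    )
    logger.info("stage=simulate_image n_cells=%d size=%dx%d seed=%d", n_cells, width, height, seed)
    return (bf, fitc), truth
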