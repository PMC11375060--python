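"""Synthetic-data generators for every pipeline input.

Each generator draws from an independent named sub-stream of the global seed
(``SeedSequence([seed, stream_id])``), so adding or re-running one generator
never perturbs the draws of another.  The statistical structure is exactly
what the downstream estimators assume:

* cohort — log2 expression with additive Gaussian noise, planted mean shifts
  in the triple-negative (TNBC) subtype, and exponential survival times whose
  per-subject rate is ``baseline_hazard * exp(beta' z)`` with ``z`` the
  standardized expression of the planted prognostic genes (proportional
  hazards by construction);
* cell-line panel — a shared latent factor per line induces the planted
  gene-module <-> metabolite-block correlation structure (glycolytic module
  positive with glycolytic metabolites, negative with fatty-acid-oxidation
  metabolites, and vice versa);
* regulation table — per-gene direction is Bernoulli(p_down) with sign-
  consistent log2 fold changes;
* cell images — disc-shaped cells whose marker intensity is split between a
  boundary rim of fixed physical width and the interior, with a ground-truth
  label mask.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig
from .datatypes import CellImage, CellLinePanel, CohortTable, RegulationTable

_STREAMS = {"cohort": 1, "panel": 2, "regulation": 3, "images": 4}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


def gene_names(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


# --------------------------------------------------------------------------
# cohort


def _draw_covariates(rng: np.random.Generator, subtype: np.ndarray) -> pd.DataFrame:
    """Clinical covariates with fixed documented marginals.

    age ~ Normal(60, 10) truncated to [25, 90]; tumor size (mm) ~
    LogNormal(log 22, 0.45); nodal status ~ Bernoulli(0.4); grade ordinal
    1-3 with probabilities (0.15, 0.45, 0.40); receptor status follows the
    subtype (TNBC = triple negative by definition).
    """
    n = len(subtype)
    age = np.clip(rng.normal(60.0, 10.0, n), 25.0, 90.0)
    size = np.exp(rng.normal(np.log(22.0), 0.45, n))
    nodes = rng.random(n) < 0.40
    grade = rng.choice([1, 2, 3], size=n, p=[0.15, 0.45, 0.40])

    is_tnbc = subtype == "TNBC"
    er = np.where(is_tnbc, 0, (rng.random(n) < 0.85).astype(int))
    pgr = np.where(is_tnbc, 0, (rng.random(n) < 0.70).astype(int))
    her2 = np.where(
        subtype == "HER2", 1, np.where(is_tnbc, 0, (rng.random(n) < 0.10).astype(int))
    )
    hormone = ((er == 1) | (pgr == 1)).astype(int)
    return pd.DataFrame(
        {
            "age": age,
            "tumor_size": size,
            "nodal_status": nodes.astype(int),
            "grade": grade,
            "er": er,
            "pgr": pgr,
            "her2": her2,
            "hormone_receptor": hormone,
        }
    )


def simulate_cohort(config: SimConfig) -> CohortTable:
    """Generate a clinical cohort with planted subtype and hazard effects.

    Survival times are exponential with rate
    ``baseline_hazard * exp(sum_g beta_g * z_g)`` where ``z_g`` is the
    standardized expression of planted gene ``g``; censoring is an
    independent exponential clock capped at ``max_followup`` years.
    """
    rng = _rng(config, "cohort")
    n, g = config.n_samples, config.n_genes
    genes = gene_names(g)
    for name in (*config.planted_subtype_log2fc, *config.planted_log_hr):
        if name not in genes:
            raise ConfigurationError(f"planted gene {name!r} not among generated genes")

    props = config.subtype_proportions
    subtype = rng.choice(list(props), size=n, p=np.asarray(list(props.values())))
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    base = rng.normal(8.0, 1.5, size=g)  # per-gene mean log2 intensity
    expr = base[:, None] + rng.normal(0.0, 1.0, size=(g, n))
    expr_df = pd.DataFrame(expr, index=genes, columns=sample_ids)
    tnbc = subtype == "TNBC"
    for gene, shift in config.planted_subtype_log2fc.items():
        expr_df.loc[gene, tnbc] += shift

    # proportional-hazards survival with planted per-SD log hazard ratios
    log_rel_hazard = np.zeros(n)
    for gene, beta in config.planted_log_hr.items():
        vals = expr_df.loc[gene].to_numpy(float)
        z = (vals - vals.mean()) / vals.std(ddof=0)
        log_rel_hazard += beta * z
    rate = config.baseline_hazard * np.exp(log_rel_hazard)
    event_time = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    censor_time = np.minimum(censor_time, config.max_followup)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-6)  # guard: survival times strictly positive

    samples = _draw_covariates(rng, subtype)
    samples.index = pd.Index(sample_ids, name="sample")
    samples.insert(0, "subtype", subtype)
    samples["time"] = time
    samples["event"] = event
    return CohortTable(expression=expr_df, samples=samples)


# --------------------------------------------------------------------------
# cell-line panel


def _split_blocks(names: list[str], blocks: list[str]) -> pd.Series:
    """Assign ~40/40/20% of items to the two named blocks and 'null'."""
    n = len(names)
    k = int(round(0.4 * n))
    labels = [blocks[0]] * k + [blocks[1]] * k + ["null"] * (n - 2 * k)
    return pd.Series(labels[:n], index=names)


def simulate_cellline_panel(config: SimConfig) -> CellLinePanel:
    """Generate paired expression / log10-metabolite matrices over cell lines.

    A standard-normal latent factor per line carries the planted structure:
    genes of module *m* load with ``+sqrt(r)`` (glycolytic) or ``-sqrt(r)``
    (FAO), metabolites of each block likewise, so every (module gene, block
    metabolite) pair has correlation ``+-r`` with the sign of the planted
    two-block design.
    """
    if config.n_lines < 6:
        raise ConfigurationError("n_lines must be >= 6 for tertile stratification")
    rng = _rng(config, "panel")
    lines = [f"L{i + 1:03d}" for i in range(config.n_lines)]
    genes = gene_names(config.n_genes)
    metabolites = [f"M{i + 1:04d}" for i in range(config.n_metabolites)]

    modules = list(config.block_structure) or ["glycolytic", "fao"]
    if len(modules) != 2:
        raise ConfigurationError("block_structure must name exactly two modules")
    gene_modules = _split_blocks(genes, modules)
    metabolite_blocks = _split_blocks(metabolites, modules)

    u = rng.standard_normal(config.n_lines)  # latent metabolic axis per line
    sign = {modules[0]: 1.0, modules[1]: -1.0, "null": 0.0}

    def loaded(labels: pd.Series, n_rows: int) -> np.ndarray:
        out = np.empty((n_rows, config.n_lines))
        for i, lab in enumerate(labels):
            r = abs(config.block_structure.get(lab, 0.0))
            load = sign[lab] * np.sqrt(r)
            noise = np.sqrt(max(1.0 - r, 0.0))
            out[i] = load * u + noise * rng.standard_normal(config.n_lines)
        return out

    expr = 5.0 + 1.0 * loaded(gene_modules, config.n_genes)
    metab = 1.5 + 0.3 * loaded(metabolite_blocks, config.n_metabolites)  # log10 scale
    return CellLinePanel(
        expression=pd.DataFrame(expr, index=genes, columns=lines),
        metabolites=pd.DataFrame(metab, index=metabolites, columns=lines),
        gene_modules=gene_modules,
        metabolite_blocks=metabolite_blocks,
    )


# --------------------------------------------------------------------------
# regulation table


def simulate_regulation_table(config: SimConfig) -> RegulationTable:
    """Generate a differential-regulation table with Bernoulli(p_down) signs."""
    rng = _rng(config, "regulation")
    n = config.n_regulated
    down = rng.random(n) < config.p_down
    magnitude = np.abs(rng.normal(0.5, 0.4, n)) + 1e-6
    log2fc = np.where(down, -magnitude, magnitude)
    # larger effects tend to smaller FDR; exact shape immaterial downstream
    fdr = rng.random(n) ** (1.0 + np.abs(log2fc))
    table = pd.DataFrame(
        {
            "gene": [f"R{i + 1:05d}" for i in range(n)],
            "log2fc": log2fc,
            "fdr": fdr,
            "direction": np.where(down, "down", "up"),
        }
    )
    return RegulationTable(table)


# --------------------------------------------------------------------------
# cell images


def simulate_cell_images(
    config: SimConfig,
    rim_thickness_nm: float = 600.0,
    n_z: int = 1,
) -> tuple[CellImage, np.ndarray]:
    """Generate disc-shaped cells with a membrane-localized marker fraction.

    Each cell's marker intensity is split: ``membrane_fraction`` of the total
    is spread uniformly over a boundary rim of physical width
    ``rim_thickness_nm`` and the rest uniformly over the whole cell, so
    ``membrane_fraction = 0`` yields a uniform marker.  Cells are placed by
    rejection sampling so that no cell overlaps another or the image border.
    Returns the multi-channel image and a ground-truth uint16 label mask.
    """
    from .imaging import corona_mask  # local import to avoid a cycle

    size = config.image_size_px
    if size < 64:
        raise ConfigurationError("image_size_px must be >= 64")
    rng = _rng(config, "images")
    depth_px = max(1, round(rim_thickness_nm / config.pixel_size_nm))
    radius0 = max(size // 12, depth_px + 3)

    labels = np.zeros((size, size), dtype=np.uint16)
    yy, xx = np.mgrid[0:size, 0:size]
    placed = 0
    for cell in range(1, config.cells_per_image + 1):
        for _ in range(2000):
            r = radius0 * rng.uniform(0.8, 1.2)
            margin = r + 2
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            if not (labels[disc] != 0).any():
                labels[disc] = cell
                placed += 1
                break
        else:
            raise ConfigurationError(
                f"could not place cell {cell} without overlap; reduce "
                f"cells_per_image or increase image_size_px"
            )
    assert placed == config.cells_per_image

    marker = np.zeros((size, size))
    actin = np.zeros((size, size))
    nuclei = np.zeros((size, size))
    total_per_cell = 50_000.0
    mf = config.membrane_fraction
    for cell in range(1, config.cells_per_image + 1):
        cell_mask = labels == cell
        rim = corona_mask(cell_mask, rim_thickness_nm, config.pixel_size_nm) > 0
        n_cell, n_rim = cell_mask.sum(), rim.sum()
        marker[cell_mask] += (1.0 - mf) * total_per_cell / n_cell
        marker[rim] += mf * total_per_cell / n_rim
        actin[cell_mask] = 100.0
        cy, cx = np.argwhere(cell_mask).mean(axis=0)
        r_nuc = max(2.0, np.sqrt(n_cell / np.pi) / 3.0)
        nuclei[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_nuc**2] = 200.0

    channels: dict[str, np.ndarray] = {"marker": marker, "actin": actin, "nuclei": nuclei}
    if config.image_noise_sd > 0:
        for name, ch in channels.items():
            channels[name] = np.clip(
                ch + rng.normal(0.0, config.image_noise_sd, ch.shape), 0.0, None
            )
    if n_z > 1:
        channels = {
            name: np.repeat(ch[None, :, :], n_z, axis=0) for name, ch in channels.items()
        }
    return CellImage(channels=channels, pixel_size_nm=config.pixel_size_nm), labels
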