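"""Seeded synthetic nodule cohorts for testing the habitat pipeline.

Real lung-adenocarcinoma CT cohorts are not redistributable, so this module
generates nodules whose internal structure carries the statistical signal the
analysis assumes: each lesion is a mixture of three density components —

* ``dense``        (mean −72.6 HU): the sub-solid, cell-packed portion,
* ``air_like``     (mean −827.25 HU): aerated, lepidic/alveolar tissue,
* ``intermediate`` (mean −424.05 HU): mixed-density tissue,

placed as spatially coherent blobs via thresholded smoothed random fields.
High-grade lesions carry a larger dense fraction, a smaller air-like
fraction, and push the little remaining air-like tissue toward the lesion
periphery — consolidated growth displacing lepidic architecture — which
lowers the air↔intermediate interface share relative to low-grade lesions.

All randomness flows from one master seed through named child streams
(geometry, intensities, covariates, assignment) so components can be
regenerated independently and byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, LesionMask, save_nifti_pair

__all__ = [
    "ComponentSpec",
    "NoduleRecipe",
    "CohortRecipe",
    "NoduleTruth",
    "CohortResult",
    "generate_nodule",
    "generate_cohort",
    "default_components",
]

COMPONENT_NAMES = ("dense", "air_like", "intermediate")

#: Canonical component attenuations (HU) for the three density phenotypes.
COMPONENT_MEANS_HU = {"dense": -72.6, "air_like": -827.25, "intermediate": -424.05}
#: Within-component voxel HU spread: tissue heterogeneity plus CT noise.
COMPONENT_SD_HU = {"dense": 90.0, "air_like": 110.0, "intermediate": 120.0}

#: Default component volume fractions per grade, anchored to the observed
#: pattern that high-grade lesions are dominated by the dense component and
#: contain almost no air-like tissue, while low-grade lesions are mostly
#: intermediate-density with an appreciable aerated share.
GRADE_FRACTIONS = {
    "low": {"dense": 0.18, "air_like": 0.12, "intermediate": 0.70},
    "high": {"dense": 0.62, "air_like": 0.03, "intermediate": 0.35},
}

#: Strength of the centre-seeking bias of the dense component (equivalently,
#: peripheral placement of air-like tissue). High grade: strongly layered.
GRADE_PERIPHERAL_WEIGHT = {"low": 0.3, "high": 1.5}


class DegenerateGeometryError(ValueError):
    """Requested nodule too small for the voxel grid."""


@dataclass(frozen=True)
class ComponentSpec:
    """One density component of a nodule."""

    name: str
    mean_hu: float
    sd_hu: float
    target_fraction: float

    def __post_init__(self) -> None:
        if self.name not in COMPONENT_NAMES:
            raise ValueError(f"unknown component {self.name!r}")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be non-negative")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")


def default_components(grade: str) -> tuple[ComponentSpec, ComponentSpec, ComponentSpec]:
    """The three canonical components with grade-dependent volume fractions."""
    fr = GRADE_FRACTIONS[grade]
    return tuple(
        ComponentSpec(n, COMPONENT_MEANS_HU[n], COMPONENT_SD_HU[n], fr[n])
        for n in COMPONENT_NAMES
    )


def _validate_components(specs) -> dict[str, ComponentSpec]:
    by_name = {s.name: s for s in specs}
    if set(by_name) != set(COMPONENT_NAMES):
        raise ValueError("component_specs must name dense, air_like, intermediate")
    total = sum(s.target_fraction for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"target fractions must sum to 1 (got {total})")
    if not (
        by_name["dense"].mean_hu
        > by_name["intermediate"].mean_hu
        > by_name["air_like"].mean_hu
    ):
        raise ValueError("component means must be ordered dense > intermediate > air_like")
    return by_name


@dataclass(frozen=True)
class NoduleRecipe:
    """Everything needed to synthesize one nodule deterministically.

    ``interface_scale`` (mm) is the correlation length of the smoothed random
    field that places components: larger values give coarser, blobbier
    habitats; smaller values give finer mixing and more inter-component
    interface. ``peripheral_air_weight`` biases low-density components toward
    the lesion boundary (``None`` selects the grade default).
    """

    grade: str = "low"
    diameter_mm: float = 18.0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    component_specs: tuple[ComponentSpec, ...] | None = None
    interface_scale: float = 3.0
    peripheral_air_weight: float | None = None
    background_hu: float = -850.0
    background_sd_hu: float = 20.0
    seed: int = 0

    def resolved_components(self) -> dict[str, ComponentSpec]:
        specs = self.component_specs or default_components(self.grade)
        return _validate_components(specs)

    def __post_init__(self) -> None:
        if self.grade not in ("low", "high"):
            raise ValueError("grade must be 'low' or 'high'")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.interface_scale <= 0:
            raise ValueError("interface_scale must be positive")
        self.resolved_components()


@dataclass
class NoduleTruth:
    """Ground-truth component layout of a generated nodule."""

    fractions: dict[str, float]
    component_labels: np.ndarray  # 0 outside mask; 1=dense, 2=air_like, 3=intermediate


def _smooth_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_nodule(recipe: NoduleRecipe) -> tuple[CTVolume, LesionMask, NoduleTruth]:
    """Synthesize one nodule: HU volume, lesion mask, and component truth.

    The mask is a single 6-connected, hole-free blob (a sphere with smooth
    radial perturbation). In-mask voxels are partitioned into the three
    components by ranking a smoothed random field — optionally biased by
    distance to the lesion surface — and cutting at the target-fraction
    quantiles, so realized fractions match targets to within one voxel.
    """
    comps = recipe.resolved_components()
    spacing = np.asarray(recipe.spacing_mm, dtype=float)
    radius_vox = recipe.diameter_mm / 2.0 / spacing
    if np.any(2 * radius_vox < 3):
        raise DegenerateGeometryError(
            f"diameter {recipe.diameter_mm} mm spans fewer than 3 voxels at "
            f"spacing {tuple(spacing)}"
        )

    ss = np.random.SeedSequence(recipe.seed)
    rng_geom, rng_field, rng_hu = (np.random.default_rng(c) for c in ss.spawn(3))

    margin = 3
    shape = tuple(int(np.ceil(2 * r)) + 2 * margin for r in radius_vox)
    center = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r_norm = np.sqrt(
        sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radius_vox))
    )
    sigma_vox = recipe.interface_scale / spacing
    bump = _smooth_field(rng_geom, shape, sigma_vox)
    mask_arr = r_norm + 0.12 * bump <= 1.0
    # Guarantee a single 6-connected, hole-free component.
    lab, n_lab = ndimage.label(mask_arr)  # default structure = 6-connectivity
    if n_lab == 0:
        raise DegenerateGeometryError("perturbed geometry produced an empty mask")
    if n_lab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n_lab + 1))
        mask_arr = lab == (1 + int(np.argmax(sizes)))
    mask_arr = ndimage.binary_fill_holes(mask_arr)
    n_vox = int(mask_arr.sum())
    if n_vox < 30:
        raise DegenerateGeometryError(f"mask has only {n_vox} voxels (< 30)")

    # Component placement field: smoothed noise + optional centrality bias.
    weight = (
        recipe.peripheral_air_weight
        if recipe.peripheral_air_weight is not None
        else GRADE_PERIPHERAL_WEIGHT[recipe.grade]
    )
    f = _smooth_field(rng_field, shape, sigma_vox)
    depth = ndimage.distance_transform_edt(mask_arr, sampling=spacing)
    dmax = depth.max()
    if dmax > 0 and weight != 0:
        cent = depth / dmax
        cent_in = cent[mask_arr]
        sd = cent_in.std()
        if sd > 0:
            f = f + weight * (cent - cent_in.mean()) / sd

    # Rank in-mask voxels: low field values -> air_like (peripheral when the
    # centrality bias is on), high -> dense, middle -> intermediate.
    in_idx = np.nonzero(mask_arr)
    order = np.argsort(f[in_idx], kind="stable")
    n_air = int(round(comps["air_like"].target_fraction * n_vox))
    n_dense = int(round(comps["dense"].target_fraction * n_vox))
    n_dense = min(n_dense, n_vox - n_air)
    comp_code = np.full(n_vox, 3, dtype=np.int8)  # intermediate
    comp_code[order[:n_air]] = 2  # air_like
    if n_dense > 0:
        comp_code[order[-n_dense:]] = 1  # dense

    labels = np.zeros(shape, dtype=np.int8)
    labels[in_idx] = comp_code

    hu = rng_hu.normal(recipe.background_hu, recipe.background_sd_hu, size=shape)
    code_to_name = {1: "dense", 2: "air_like", 3: "intermediate"}
    for code, name in code_to_name.items():
        sel = labels == code
        n_sel = int(sel.sum())
        if n_sel:
            spec = comps[name]
            hu[sel] = rng_hu.normal(spec.mean_hu, spec.sd_hu, size=n_sel)

    truth = NoduleTruth(
        fractions={
            name: float((labels == code).sum()) / n_vox
            for code, name in code_to_name.items()
        },
        component_labels=labels,
    )
    vol = CTVolume(hu, tuple(spacing), (0.0, 0.0, 0.0), "HU")
    mask = LesionMask(mask_arr, tuple(spacing), (0.0, 0.0, 0.0))
    return vol, mask, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Grade-conditional covariate marginals pooled from the kind of baseline
#: table this analysis consumes (categorical levels with probabilities, or
#: ("lognormal", median, sigma) for skewed continuous variables).
DEFAULT_COVARIATE_MODEL = {
    "gender": {
        "levels": ("male", "female"),
        "low": (0.367, 0.633),
        "high": (0.561, 0.439),
    },
    "age": {"normal": {"low": (63.0, 9.0), "high": (62.0, 10.0)}},
    "smoking_history": {
        "levels": ("long_term", "ever", "never"),
        "low": (0.173, 0.232, 0.595),
        "high": (0.318, 0.106, 0.576),
    },
    "alcohol_consumption": {
        "levels": ("heavy", "light", "never"),
        "low": (0.135, 0.228, 0.637),
        "high": (0.167, 0.257, 0.576),
    },
    "clinical_stage": {
        "levels": ("I", "II", "III"),
        "low": (0.765, 0.152, 0.083),
        "high": (0.500, 0.333, 0.167),
    },
    "involved_lobe": {
        "levels": ("LUL", "LLL", "RUL", "RML", "RLL"),
        "low": (0.256, 0.131, 0.318, 0.069, 0.226),
        "high": (0.242, 0.227, 0.334, 0.061, 0.136),
    },
    "tumor_shape": {
        "levels": ("round_oval", "irregular"),
        "low": (0.066, 0.934),
        "high": (0.152, 0.848),
    },
    "attenuation": {
        "levels": ("solid", "part_solid", "ground_glass"),
        "low": (0.367, 0.488, 0.145),
        "high": (0.803, 0.182, 0.015),
    },
    "lobulation": {"levels": ("yes", "no"), "low": (0.823, 0.177), "high": (0.955, 0.045)},
    "air_bronchogram": {"levels": ("yes", "no"), "low": (0.377, 0.623), "high": (0.439, 0.561)},
    "spiculation": {"levels": ("yes", "no"), "low": (0.540, 0.460), "high": (0.864, 0.136)},
    "pleural_tag": {"levels": ("yes", "no"), "low": (0.713, 0.287), "high": (0.894, 0.106)},
    "cavity": {"levels": ("yes", "no"), "low": (0.048, 0.952), "high": (0.045, 0.955)},
    "diameter_mm": {"lognormal": {"low": (16.5, 0.32), "high": (21.5, 0.30)}},
}


@dataclass(frozen=True)
class CohortRecipe:
    """Cohort sizes, prevalence and generator knobs for a full study."""

    n_train: int = 161
    n_val: int = 66
    n_test: int = 128
    prevalence_high: float = 0.186
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    interface_scale: float = 3.0
    fraction_concentration: float = 30.0
    diameter_range_mm: tuple[float, float] = (9.0, 38.0)
    covariate_model: dict = field(default_factory=lambda: DEFAULT_COVARIATE_MODEL)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 <= self.prevalence_high < 1.0:
            raise ValueError("prevalence_high must lie in [0, 1)")
        if self.fraction_concentration <= 0:
            raise ValueError("fraction_concentration must be positive")


@dataclass
class CohortResult:
    """A generated cohort: covariate table plus per-case images and truths."""

    table: pd.DataFrame
    volumes: list[CTVolume]
    masks: list[LesionMask]
    truths: list[NoduleTruth]


def _draw_covariates(rng: np.random.Generator, model: dict, grade: str) -> dict:
    row = {}
    for name, spec in model.items():
        if "levels" in spec:
            levels = spec["levels"]
            p = np.asarray(spec[grade], dtype=float)
            row[name] = levels[rng.choice(len(levels), p=p / p.sum())]
        elif "normal" in spec:
            mu, sd = spec["normal"][grade]
            row[name] = float(np.round(rng.normal(mu, sd), 1))
        elif "lognormal" in spec:
            med, sigma = spec["lognormal"][grade]
            row[name] = float(np.round(med * np.exp(rng.normal(0.0, sigma)), 1))
        else:  # pragma: no cover - schema guard
            raise ValueError(f"unrecognized covariate spec for {name!r}")
    return row


def _case_fractions(rng: np.random.Generator, grade: str, conc: float) -> dict[str, float]:
    target = np.array([GRADE_FRACTIONS[grade][n] for n in COMPONENT_NAMES])
    # Dirichlet jitter around the grade target: inter-patient variability in
    # component composition while preserving the grade-level means.
    alpha = np.maximum(target * conc, 0.05)
    frac = rng.dirichlet(alpha)
    return dict(zip(COMPONENT_NAMES, frac))


def generate_cohort(
    recipe: CohortRecipe,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> CohortResult:
    """Generate a full training/validation/test cohort.

    Each cohort receives ``round(prevalence_high * n)`` high-grade cases; the
    per-case component fractions are Dirichlet-jittered around the grade
    defaults, and the nodule diameter is shared between the covariate table
    and the image geometry. If ``out_dir`` is given, images and masks are
    written as NIfTI pairs and the table (plus a column dictionary) as text;
    an existing non-empty directory is refused unless ``overwrite``.
    """
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        if out_path.exists() and any(out_path.iterdir()) and not overwrite:
            raise FileExistsError(
                f"{out_path} exists and is not empty; pass overwrite=True"
            )
        out_path.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(recipe.seed)
    ss_assign, ss_cov, ss_img = ss.spawn(3)
    rng_assign = np.random.default_rng(ss_assign)
    rng_cov = np.random.default_rng(ss_cov)

    cohorts = [("train", recipe.n_train), ("val", recipe.n_val), ("test", recipe.n_test)]
    rows = []
    for cohort, n in cohorts:
        n_high = int(round(recipe.prevalence_high * n))
        grades = np.array(["high"] * n_high + ["low"] * (n - n_high))
        rng_assign.shuffle(grades)
        for g in grades:
            rows.append({"cohort": cohort, "grade": g})

    n_total = len(rows)
    img_seeds = ss_img.spawn(n_total)
    volumes, masks, truths = [], [], []
    lo, hi = recipe.diameter_range_mm
    for i, row in enumerate(rows):
        grade = row["grade"]
        cov = _draw_covariates(rng_cov, recipe.covariate_model, grade)
        cov["diameter_mm"] = float(np.clip(cov["diameter_mm"], lo, hi))
        frac = _case_fractions(rng_cov, grade, recipe.fraction_concentration)
        specs = tuple(
            ComponentSpec(n, COMPONENT_MEANS_HU[n], COMPONENT_SD_HU[n], frac[n])
            for n in COMPONENT_NAMES
        )
        # spawned child entropy folded into one 31-bit per-case seed
        case_seed = int(img_seeds[i].generate_state(1)[0] % (2**31 - 1))
        nod = NoduleRecipe(
            grade=grade,
            diameter_mm=cov["diameter_mm"],
            spacing_mm=recipe.spacing_mm,
            component_specs=specs,
            interface_scale=recipe.interface_scale,
            seed=case_seed,
        )
        vol, mask, truth = generate_nodule(nod)
        volumes.append(vol)
        masks.append(mask)
        truths.append(truth)
        row.update(cov)
        row["patient_id"] = f"case_{i:04d}"
        for name in COMPONENT_NAMES:
            row[f"truth_frac_{name}"] = truth.fractions[name]

    table = pd.DataFrame(rows)
    front = ["patient_id", "cohort", "grade"]
    table = table[front + [c for c in table.columns if c not in front]]

    if out_path is not None:
        for i, row in table.iterrows():
            pid = row["patient_id"]
            img_p = out_path / f"{pid}_image.nii.gz"
            msk_p = out_path / f"{pid}_mask.nii.gz"
            save_nifti_pair(volumes[i], masks[i], img_p, msk_p)
            table.loc[i, "image_path"] = str(img_p)
            table.loc[i, "mask_path"] = str(msk_p)
        table.to_csv(out_path / "covariates.csv", index=False)
        _write_column_dictionary(out_path / "covariate_dictionary.md", recipe)

    return CohortResult(table, volumes, masks, truths)


def _write_column_dictionary(path: Path, recipe: CohortRecipe) -> None:
    lines = [
        "# Covariate table column dictionary",
        "",
        "- patient_id: unique case identifier",
        "- cohort: train / val / test split assignment",
        "- grade: histological grade group (low / high)",
    ]
    for name, spec in recipe.covariate_model.items():
        if "levels" in spec:
            lines.append(f"- {name}: categorical, levels {', '.join(spec['levels'])}")
        else:
            unit = " (mm)" if name.endswith("_mm") else " (years)" if name == "age" else ""
            lines.append(f"- {name}: continuous{unit}")
    lines += [
        "- truth_frac_dense / truth_frac_air_like / truth_frac_intermediate: "
        "generator ground-truth component volume fractions",
        "- image_path / mask_path: NIfTI image and lesion mask for the case",
    ]
    path.write_text("\n".join(lines) + "\n")
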