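"""Synthetic fluorescence fields and screening plates with exact ground truth.

This module emulates the statistical structure of a 384-well high-content
lipid-droplet (LD) screen on patient fibroblasts: a nuclear channel, a
whole-cell channel and a puncta (LD) channel per field, a plate layout with
negative-control wells (patient + vehicle), positive-control wells (healthy
control lines + vehicle) and compound wells, and per-well values of the four
LD screen parameters (mean LD area, total LD area per cell, compactness and
form factor).

Two generation routes are provided:

* ``render_field`` draws an actual multi-channel image (elliptical cells with
  interior nuclei, disk-shaped LDs, Gaussian PSF blur, additive noise) plus an
  exact object-level ground truth, for exercising segmentation.
* ``simulate_well_features`` / ``build_plate(mode="features")`` skip rendering
  and draw the four well-level parameters directly around their closed-form
  expectations, for exercising plate statistics at scale.

LD counts per cell are Poisson(lambda) and LD radii log-normal, so all
well-level expectations have closed forms (e.g. expected total LD area per
cell = lambda * pi * median^2 * exp(2 sigma^2) in px^2), which the tests use
as independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .imaging import ImageSet
from .morphometry import WellSummary

__all__ = [
    "PARAMETERS",
    "BASELINE_COMPACTNESS",
    "SceneSpec",
    "PhenotypeProfile",
    "PlateSpec",
    "GroundTruth",
    "CellRecord",
    "LDRecord",
    "PlacementError",
    "PROFILES",
    "NULL_PROFILE",
    "expected_parameters",
    "default_noise_model",
    "render_field",
    "simulate_well_features",
    "build_plate",
    "make_default_plate",
    "simulate_organelle_groups",
]

#: The four per-well LD screen parameters, in canonical order.
PARAMETERS = ("ld_area", "ld_total_area", "ld_compactness", "ld_form_factor")

#: Feature-mode baseline for mean LD compactness (P^2 / 4*pi*A). Digitised
#: near-circular droplets sit slightly above the analytic circle value of 1.
BASELINE_COMPACTNESS = 1.15


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed in the field without overlap."""


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic field.

    Defaults describe the patient (disease) phenotype: many bright LDs per
    cell. Lengths are in pixels unless noted; intensities are arbitrary units.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.65  # micrometres per pixel
    n_cells: int = 6
    cell_radius_range: tuple[float, float] = (26.0, 34.0)  # semi-major axis, px
    nucleus_radius_fraction: float = 0.3
    ld_count_mean: float = 8.0  # Poisson rate per cell
    ld_radius_median: float = 3.0  # px; radii are log-normal
    ld_radius_sigma: float = 0.2  # log-space SD
    channel_intensities: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "nucleus": (180.0, 8.0),
            "cell": (70.0, 8.0),
            "puncta": (200.0, 10.0),
        }
    )
    noise_sd: float = 4.0
    psf_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError(f"non-positive image shape {self.image_shape}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.ld_count_mean < 0:
            raise ValueError("ld_count_mean must be >= 0")
        if self.ld_radius_median <= 0:
            raise ValueError("ld_radius_median must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        for name, (fg, bg) in self.channel_intensities.items():
            if fg < 0 or bg < 0:
                raise ValueError(f"negative intensity for channel {name!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhenotypeProfile:
    """Multiplicative phenotype acting on the LD population of a scene.

    ``ld_count_multiplier`` scales the Poisson rate, ``ld_radius_multiplier``
    the log-normal radius median. ``param_shift_sd`` is a feature-mode-only
    knob mapping parameter name -> displacement in units of that parameter's
    well noise SD; a shifted parameter is placed exactly at
    ``expectation + shift * noise_sd`` (no noise draw), giving planted effects
    of known, exact magnitude for recovery benchmarking.
    """

    name: str
    ld_count_multiplier: float = 1.0
    ld_radius_multiplier: float = 1.0
    param_shift_sd: Mapping[str, float] | None = None

    def validate(self) -> None:
        if self.ld_count_multiplier < 0 or self.ld_radius_multiplier <= 0:
            raise ValueError("profile multipliers must be positive")
        if self.param_shift_sd:
            unknown = set(self.param_shift_sd) - set(PARAMETERS)
            if unknown:
                raise ValueError(f"unknown parameters in param_shift_sd: {unknown}")

    @property
    def is_null(self) -> bool:
        return (
            self.ld_count_multiplier == 1.0
            and self.ld_radius_multiplier == 1.0
            and not self.param_shift_sd
        )


NULL_PROFILE = PhenotypeProfile("null")

#: Preset phenotypes. ``patient`` is the disease baseline (scene defaults);
#: ``control`` is the healthy-fibroblast phenotype with few LDs. The compound
#: archetypes mirror the effect classes seen in the screen: clearance
#: (fewer and smaller LDs), fewer-but-larger remaining LDs, null, and
#: accumulation.
PROFILES: dict[str, PhenotypeProfile] = {
    "patient": PhenotypeProfile("patient"),
    "control": PhenotypeProfile("control", ld_count_multiplier=0.15),
    "null": NULL_PROFILE,
    "ld_clearance": PhenotypeProfile("ld_clearance", 0.3, 0.7),
    "fewer_larger": PhenotypeProfile("fewer_larger", 0.4, 1.4),
    "ld_accumulation": PhenotypeProfile("ld_accumulation", 1.5, 1.2),
}


@dataclass
class CellRecord:
    label: int
    center: tuple[float, float]  # (row, col) px
    axes: tuple[float, float]  # (semi-major, semi-minor) px
    angle: float  # radians, CCW


@dataclass
class LDRecord:
    center: tuple[float, float]  # (row, col) px
    radius: float  # px
    parent: int  # cell label

    @property
    def area(self) -> float:
        return math.pi * self.radius**2


@dataclass
class GroundTruth:
    """Exact object-level truth for one rendered field."""

    cells: list[CellRecord]
    lds: list[LDRecord]
    expected: dict[str, float]  # closed-form well-level expectations (um^2)
    nucleus_radius_fraction: float = 0.4

    @property
    def ld_total_area_px(self) -> float:
        return float(sum(ld.area for ld in self.lds))

    def cell_labels(self, shape: tuple[int, int]) -> np.ndarray:
        lab = np.zeros(shape, dtype=np.int32)
        for c in self.cells:
            rr, cc = skdraw.ellipse(
                c.center[0], c.center[1], c.axes[0], c.axes[1], shape=shape,
                rotation=c.angle,
            )
            lab[rr, cc] = c.label
        return lab

    def nucleus_labels(self, shape: tuple[int, int]) -> np.ndarray:
        lab = np.zeros(shape, dtype=np.int32)
        f = self.nucleus_radius_fraction
        for c in self.cells:
            rr, cc = skdraw.ellipse(
                c.center[0], c.center[1], c.axes[0] * f, c.axes[1] * f,
                shape=shape, rotation=c.angle,
            )
            lab[rr, cc] = c.label
        return lab

    def ld_labels(self, shape: tuple[int, int]) -> np.ndarray:
        lab = np.zeros(shape, dtype=np.int32)
        for i, ld in enumerate(self.lds, start=1):
            rr, cc = skdraw.disk(ld.center, ld.radius, shape=shape)
            lab[rr, cc] = i
        return lab


def expected_parameters(spec: SceneSpec, profile: PhenotypeProfile = NULL_PROFILE) -> dict[str, float]:
    """Closed-form expectations of the four well parameters under a profile.

    With LD count ~ Poisson(lambda * cm) and radius ~ LogNormal(ln(m * rm),
    sigma): E[per-LD area] = pi (m rm)^2 e^{2 sigma^2} and E[total area per
    cell] = lambda cm * E[per-LD area]. Areas are returned in um^2 via
    ``pixel_size``. Compactness/form factor are scale-free baselines.
    """
    m = spec.ld_radius_median * profile.ld_radius_multiplier
    lam = spec.ld_count_mean * profile.ld_count_multiplier
    mean_area_px = math.pi * m**2 * math.exp(2 * spec.ld_radius_sigma**2)
    um2 = spec.pixel_size**2
    return {
        "ld_area": mean_area_px * um2,
        "ld_total_area": lam * mean_area_px * um2,
        "ld_compactness": BASELINE_COMPACTNESS,
        "ld_form_factor": 1.0 / BASELINE_COMPACTNESS,
    }


def default_noise_model(spec: SceneSpec) -> dict[str, float]:
    """Default well-to-well noise: 5% of the patient-baseline expectation."""
    exp = expected_parameters(spec, PROFILES["patient"])
    return {p: 0.05 * exp[p] for p in PARAMETERS}


# ---------------------------------------------------------------------------
# image rendering


def _inside_ellipse(dy, dx, a, b, angle):
    ca, sa = math.cos(angle), math.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> list[CellRecord]:
    h, w = spec.image_shape
    lo, hi = spec.cell_radius_range
    cells: list[CellRecord] = []
    for label in range(1, spec.n_cells + 1):
        placed = False
        for _ in range(200):
            a = rng.uniform(lo, hi)
            b = a * rng.uniform(0.8, 0.95)
            angle = rng.uniform(0.0, math.pi)
            if h - 2 * (a + 2) <= 0 or w - 2 * (a + 2) <= 0:
                raise PlacementError(
                    f"cell semi-axis {a:.1f} px does not fit in field {spec.image_shape}"
                )
            cy = rng.uniform(a + 2, h - a - 2)
            cx = rng.uniform(a + 2, w - a - 2)
            # conservative bounding-circle test keeps cells disjoint
            ok = all(
                math.hypot(cy - c.center[0], cx - c.center[1]) > a + c.axes[0] + 1
                for c in cells
            )
            if ok:
                cells.append(CellRecord(label, (cy, cx), (a, b), angle))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {label}/{spec.n_cells} after 200 attempts; "
                "reduce n_cells or cell size"
            )
    return cells


def _place_lds(
    cell: CellRecord,
    radii: Sequence[float],
    nucleus_fraction: float,
    rng: np.random.Generator,
    existing: list[LDRecord],
) -> list[LDRecord]:
    a, b = cell.axes
    cy, cx = cell.center
    out: list[LDRecord] = []
    # large droplets first: random sequential packing fits the set far more
    # often this way, keeping overlap fallbacks rare
    for r in sorted(radii, reverse=True):
        ia, ib = a - r - 1, b - r - 1  # LD fully inside the cell
        na, nb = a * nucleus_fraction + r, b * nucleus_fraction + r  # and off the nucleus
        if ia <= 0 or ib <= 0:
            raise PlacementError(f"LD radius {r:.1f} px exceeds cell size")

        def propose():
            # prefer the cytoplasmic annulus; a large droplet may leave almost
            # no annulus, in which case it may sit over the nucleus (as real
            # droplets do in 2-D projection)
            for _ in range(500):
                dy = rng.uniform(-ia, ia)
                dx = rng.uniform(-ia, ia)
                if _inside_ellipse(dy, dx, ia, ib, cell.angle) and not _inside_ellipse(
                    dy, dx, na, nb, cell.angle
                ):
                    return dy, dx
            while True:
                dy = rng.uniform(-ia, ia)
                dx = rng.uniform(-ia, ia)
                if _inside_ellipse(dy, dx, ia, ib, cell.angle):
                    return dy, dx

        rec = None
        for _ in range(200):  # phase 1: avoid overlap with siblings
            dy, dx = propose()
            y, x = cy + dy, cx + dx
            if all(
                math.hypot(y - o.center[0], x - o.center[1]) >= r + o.radius + 2.5
                for o in out
            ):
                rec = LDRecord((y, x), r, cell.label)
                break
        if rec is None:  # phase 2: overlap allowed, still in the cytoplasm
            dy, dx = propose()
            rec = LDRecord((cy + dy, cx + dx), r, cell.label)
        out.append(rec)
    existing.extend(out)
    return out


def render_field(
    spec: SceneSpec,
    profile: PhenotypeProfile = NULL_PROFILE,
    seed: int | None = None,
    well: str = "",
    field_index: int = 0,
) -> tuple[ImageSet, GroundTruth]:
    """Render one multi-channel field and its exact ground truth.

    Deterministic given ``spec`` + ``seed`` (defaults to ``spec.seed``). Four
    independent substreams are used, in order: cell placement, LD counts
    (one vectorised Poisson draw of length ``n_cells``), LD radii (one
    vectorised log-normal draw), and pixel noise — so the count draw can be
    replayed independently from the same seed.
    """
    spec.validate()
    profile.validate()
    if seed is None:
        seed = spec.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    place_rng, count_rng, radius_rng, noise_rng = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    cells = _place_cells(spec, place_rng)
    lam = spec.ld_count_mean * profile.ld_count_multiplier
    counts = count_rng.poisson(lam, size=spec.n_cells) if spec.n_cells else np.zeros(0, int)
    median = spec.ld_radius_median * profile.ld_radius_multiplier
    total = int(counts.sum())
    radii = radius_rng.lognormal(math.log(median), spec.ld_radius_sigma, size=total)

    lds: list[LDRecord] = []
    offset = 0
    for cell, k in zip(cells, counts):
        _place_lds(cell, radii[offset : offset + k], spec.nucleus_radius_fraction,
                   place_rng, lds)
        offset += k

    shape = spec.image_shape
    channels: dict[str, np.ndarray] = {}
    for name, (fg, bg) in spec.channel_intensities.items():
        img = np.full(shape, bg, dtype=np.float64)
        if name == "nucleus":
            f = spec.nucleus_radius_fraction
            for c in cells:
                rr, cc = skdraw.ellipse(*c.center, c.axes[0] * f, c.axes[1] * f,
                                        shape=shape, rotation=c.angle)
                img[rr, cc] = fg
        elif name in ("cell", "active_mito", "total_mito"):
            for c in cells:
                rr, cc = skdraw.ellipse(*c.center, c.axes[0], c.axes[1],
                                        shape=shape, rotation=c.angle)
                img[rr, cc] = fg
        elif name == "puncta":
            for ld in lds:
                rr, cc = skdraw.disk(ld.center, ld.radius, shape=shape)
                img[rr, cc] = fg
        else:
            raise ValueError(f"unknown channel {name!r}")
        channels[name] = img

    for name in sorted(channels):
        img = channels[name]
        if spec.psf_sigma > 0:
            img = ndimage.gaussian_filter(img, spec.psf_sigma)
        if spec.noise_sd > 0:
            img = img + noise_rng.normal(0.0, spec.noise_sd, size=shape)
        channels[name] = np.clip(img, 0.0, None)

    image = ImageSet(channels=channels, pixel_size=spec.pixel_size,
                     well=well, field=field_index)
    gt = GroundTruth(cells=cells, lds=lds,
                     expected=expected_parameters(spec, profile),
                     nucleus_radius_fraction=spec.nucleus_radius_fraction)
    return image, gt


# ---------------------------------------------------------------------------
# feature-level simulation


def simulate_well_features(
    profile: PhenotypeProfile,
    base: SceneSpec,
    n_fields: int = 12,
    noise_model: Mapping[str, float] | None = None,
    seed: int = 0,
    well: str = "",
) -> WellSummary:
    """Draw one well's four LD parameters around their closed-form means.

    Each parameter is ``expectation + N(0, sd)`` with the per-parameter SD
    from ``noise_model`` (default: :func:`default_noise_model`); a parameter
    named in ``profile.param_shift_sd`` is instead placed exactly at
    ``expectation + shift * sd``.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    base.validate()
    profile.validate()
    noise = dict(noise_model) if noise_model is not None else default_noise_model(base)
    for p in PARAMETERS:
        if noise.get(p, 0.0) < 0:
            raise ValueError(f"negative noise SD for {p}")
    exp = expected_parameters(base, profile)
    rng = np.random.default_rng(seed)
    shifts = dict(profile.param_shift_sd or {})
    values = {}
    for p in PARAMETERS:
        sd = noise.get(p, 0.0)
        eps = rng.normal(0.0, sd) if sd > 0 else 0.0
        if p in shifts:
            values[p] = exp[p] + shifts[p] * sd
        else:
            values[p] = exp[p] + eps
    return WellSummary(
        well=well,
        n_cells=n_fields * base.n_cells,
        ld_area=values["ld_area"],
        ld_total_area=values["ld_total_area"],
        ld_compactness=values["ld_compactness"],
        ld_form_factor=values["ld_form_factor"],
    )


# ---------------------------------------------------------------------------
# plates


@dataclass(frozen=True)
class PlateSpec:
    """Layout + generation parameters for one screening plate.

    ``positive_control_wells`` maps control cell-line name -> wells, so the
    two healthy lines used as positive controls can be scored separately.
    """

    n_rows: int = 16
    n_cols: int = 24
    negative_control_wells: tuple[str, ...] = ()
    positive_control_wells: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    compound_wells: tuple[tuple[str, str], ...] = ()  # (well, compound_id)
    fields_per_well: int = 12
    base_scene: SceneSpec = field(default_factory=SceneSpec)
    seed: int = 0

    def validate(self) -> None:
        from .io import parse_well  # local import avoids a cycle at import time

        seen: set[str] = set()
        groups = [list(self.negative_control_wells)]
        groups += [list(v) for v in self.positive_control_wells.values()]
        groups += [[w for w, _ in self.compound_wells]]
        for group in groups:
            for wname in group:
                r, c = parse_well(wname)
                if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                    raise ValueError(f"well {wname} outside {self.n_rows}x{self.n_cols} plate")
                if wname in seen:
                    raise ValueError(f"well {wname} assigned to more than one role")
                seen.add(wname)
        if self.negative_control_wells and len(self.negative_control_wells) < 2:
            raise ValueError("need >= 2 negative-control wells to estimate an SD")
        for line, wells in self.positive_control_wells.items():
            if len(wells) < 2:
                raise ValueError(f"need >= 2 positive-control wells for line {line}")
        ids = [cid for _, cid in self.compound_wells]
        dupes = {c for c in ids if ids.count(c) > 1}
        if dupes:
            raise ValueError(f"duplicate compound_id in compound wells: {sorted(dupes)}")


def _well_rows(plate: PlateSpec):
    """Yield (well, role, cell_line, compound_id) in deterministic order."""
    from .io import parse_well

    rows = []
    for w in plate.negative_control_wells:
        rows.append((w, "negative_control", "patient", "DMSO"))
    for line, wells in sorted(plate.positive_control_wells.items()):
        for w in wells:
            rows.append((w, "positive_control", line, "DMSO"))
    for w, cid in plate.compound_wells:
        rows.append((w, "compound", "patient", cid))
    rows.sort(key=lambda r: parse_well(r[0]))
    return rows


def build_plate(
    plate: PlateSpec,
    planted_effects: Mapping[str, PhenotypeProfile] | None = None,
    mode: str = "features",
    out_dir=None,
    noise_model: Mapping[str, float] | None = None,
):
    """Generate a whole plate in feature or image mode.

    Feature mode returns ``(features_df, manifest)`` where ``features_df`` has
    one row per well (identity columns + ``n_cells`` + the four parameters)
    and the manifest names every planted effect and every planted hit
    (compounds whose profile differs from the null). Image mode writes one
    multi-channel TIFF per field under ``out_dir`` and returns
    ``(field_index_df, manifest)``.
    """
    import pandas as pd

    plate.validate()
    planted = dict(planted_effects or {})
    known = {cid for _, cid in plate.compound_wells}
    unknown = set(planted) - known
    if unknown:
        raise ValueError(f"planted effects for unknown compounds: {sorted(unknown)}")

    rows = _well_rows(plate)
    children = np.random.SeedSequence(plate.seed).spawn(len(rows))

    def profile_for(role, cid):
        if role == "negative_control":
            return PROFILES["patient"]
        if role == "positive_control":
            return PROFILES["control"]
        return planted.get(cid, NULL_PROFILE)

    manifest = {
        "seed": plate.seed,
        "mode": mode,
        "fields_per_well": plate.fields_per_well,
        "n_wells": len(rows),
        "planted": {
            cid: {
                "name": p.name,
                "ld_count_multiplier": p.ld_count_multiplier,
                "ld_radius_multiplier": p.ld_radius_multiplier,
                "param_shift_sd": dict(p.param_shift_sd or {}),
            }
            for cid, p in sorted(planted.items())
        },
        "planted_hits": sorted(cid for cid, p in planted.items() if not p.is_null),
    }

    if mode == "features":
        from .io import parse_well

        recs = []
        for (wname, role, line, cid), child in zip(rows, children):
            ws = simulate_well_features(
                profile_for(role, cid), plate.base_scene, plate.fields_per_well,
                noise_model, seed=child, well=wname,
            )
            r, c = parse_well(wname)
            recs.append({
                "well": wname, "row": r, "col": c, "role": role,
                "cell_line": line, "compound_id": cid, "concentration_uM": 10.0,
                **ws.as_dict(),
            })
        df = pd.DataFrame(recs)
        return df, manifest

    if mode == "images":
        if out_dir is None:
            raise ValueError("image mode requires out_dir")
        from .io import write_field_tiff

        index = []
        gt_wells: dict[str, dict] = {}
        for (wname, role, line, cid), child in zip(rows, children):
            prof = profile_for(role, cid)
            field_seeds = child.spawn(plate.fields_per_well)
            planted_lds = 0
            planted_cells = 0
            for fi, fs in enumerate(field_seeds):
                img, gt = render_field(plate.base_scene, prof, seed=fs,
                                       well=wname, field_index=fi)
                path = write_field_tiff(out_dir, img)
                planted_lds += len(gt.lds)
                planted_cells += len(gt.cells)
                index.append({"well": wname, "field": fi, "role": role,
                              "cell_line": line, "compound_id": cid,
                              "path": str(path)})
            gt_wells[wname] = {"planted_ld_count": planted_lds,
                               "planted_cell_count": planted_cells,
                               "expected": expected_parameters(plate.base_scene, prof)}
        manifest["wells"] = gt_wells
        return pd.DataFrame(index), manifest

    raise ValueError(f"unknown mode {mode!r}")


def make_default_plate(
    n_compounds: int = 348,
    seed: int = 0,
    base_scene: SceneSpec | None = None,
    fields_per_well: int = 12,
    n_rows: int = 16,
    n_cols: int = 24,
    n_negative: int = 12,
    n_positive_per_line: int = 12,
    lines: Sequence[str] = ("GM05400", "GM05381"),
) -> PlateSpec:
    """Standard screen layout: 12 negative-control wells (patient + DMSO,
    column 1), 12 positive-control wells for each of two healthy lines
    (right-most columns), compounds filling the interior left-to-right.
    Smaller geometries (mini plates for image mode) reuse the same scheme."""
    from .io import well_name

    def column_fill(n, start_col, step):
        out, r, c = [], 0, start_col
        for _ in range(n):
            out.append(well_name(r, c))
            r += 1
            if r == n_rows:
                r, c = 0, c + step
        return tuple(out)

    neg = column_fill(n_negative, 0, 1)
    pos = {}
    col = n_cols - 1
    for line in reversed(list(lines)):
        pos[line] = column_fill(n_positive_per_line, col, -1)
        col -= max(1, -(-n_positive_per_line // n_rows))
    used = set(neg) | {w for ws in pos.values() for w in ws}
    compounds = []
    i = 1
    for r in range(n_rows):
        for c in range(n_cols):
            w = well_name(r, c)
            if w in used or len(compounds) >= n_compounds:
                continue
            compounds.append((w, f"CPD-{i:04d}"))
            i += 1
    if len(compounds) < n_compounds:
        raise ValueError(f"plate too small for {n_compounds} compounds")
    return PlateSpec(
        n_rows=n_rows, n_cols=n_cols,
        negative_control_wells=neg, positive_control_wells=pos,
        compound_wells=tuple(compounds), fields_per_well=fields_per_well,
        base_scene=base_scene or SceneSpec(), seed=seed,
    )


# ---------------------------------------------------------------------------
# organelle-population simulation (peroxisome-style two-group contrasts)


def simulate_organelle_groups(
    n_cells: int = 150,
    count_mean: float = 30.0,
    count_ratio: float = 1.3,
    size_mean_um2: float = 0.35,
    size_ratio: float = 0.8,
    size_sigma: float = 0.4,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Simulate per-cell organelle counts and per-organelle sizes for a
    patient-vs-control contrast (disease group: ``count_ratio``-fold counts,
    ``size_ratio``-fold sizes). Counts are Poisson per cell; sizes are
    log-normal with the given median (um^2) and log-space SD."""
    rng = np.random.default_rng(seed)
    counts_control = rng.poisson(count_mean, size=n_cells)
    counts_patient = rng.poisson(count_mean * count_ratio, size=n_cells)
    sizes_control = rng.lognormal(math.log(size_mean_um2), size_sigma,
                                  size=int(counts_control.sum()))
    sizes_patient = rng.lognormal(math.log(size_mean_um2 * size_ratio), size_sigma,
                                  size=int(counts_patient.sum()))
    return {
        "counts_control": counts_control,
        "counts_patient": counts_patient,
        "sizes_control": sizes_control,
        "sizes_patient": sizes_patient,
    }
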