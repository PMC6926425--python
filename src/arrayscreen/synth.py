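"""Synthetic data with ground truth for every pipeline stage.

Generates plate layouts and luminescence readouts, full two-cell-line
screens, fluorescence microscopy fields (touching nuclei, punctate
perinuclear signal) and protein-turnover tables. Every generator is a pure
function of its spec and seed: the same seed reproduces the output
bit-for-bit, and the emitted ground truth is sufficient to score the
downstream stage without re-deriving it.

Default effect sizes mirror the screen's operating regime: the lethal
positive control reduces viability to 0.15 of mock (an essential-gene
knockout killing ~85% of cells) and control wells vary with a ~5%
coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from arrayscreen.errors import PlacementError
from arrayscreen.imaging import ImageField
from arrayscreen.screen_io import (
    PLATE_FORMATS,
    WellRecord,
    rowcol_to_well,
)
from arrayscreen.turnover import LN2, remaining_fraction
from scipy.optimize import brentq


@dataclass
class PlateSimSpec:
    """Layout and generative parameters for one synthetic plate.

    Raw well luminescence follows
    ``blank_mean + (mock_mean - blank_mean) * effect * noise`` with
    log-normal multiplicative noise of coefficient of variation
    ``noise_cv`` (mean 1). Blank wells carry no signal term.
    """

    plate_format: int = 96
    n_mock: int = 6
    n_blank: int = 4
    n_scrambled: int = 8
    n_positive: int = 8
    gene_effects: dict[str, float] = dc_field(default_factory=dict)
    guides_per_gene: int = 1
    mock_mean: float = 1_100_000.0
    blank_mean: float = 2_000.0
    scrambled_effect: float = 1.0
    positive_effect: float = 0.15
    noise_cv: float = 0.05
    plate_id: str = "plate1"
    replicate: int = 1
    seed: int = 0


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int):
    """Multiplicative noise, mean 1, given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_plate(spec: PlateSimSpec):
    """One plate: returns (plate map records, readout DataFrame, truth).

    The truth table records the intended relative effect of each well.
    """
    if spec.plate_format not in PLATE_FORMATS:
        raise ValueError(f"unsupported plate format {spec.plate_format}")
    n_rows, n_cols = PLATE_FORMATS[spec.plate_format]
    capacity = n_rows * n_cols
    wells_needed = (
        spec.n_mock + spec.n_blank + spec.n_scrambled + spec.n_positive
        + len(spec.gene_effects) * spec.guides_per_gene
    )
    if wells_needed > capacity:
        raise ValueError(
            f"{wells_needed} wells requested on a {spec.plate_format}-well plate"
        )
    rng = np.random.default_rng(spec.seed)

    contents: list[tuple[str, str, str]] = []  # (content_type, gene, guide)
    contents += [("mock", "", "")] * spec.n_mock
    contents += [("blank", "", "")] * spec.n_blank
    contents += [
        ("scrambled", "", f"scr_{i+1:02d}") for i in range(spec.n_scrambled)
    ]
    contents += [
        ("positive_control", "POLR2A", f"polr2a_g{i+1}")
        for i in range(spec.n_positive)
    ]
    for gene in spec.gene_effects:
        for g in range(spec.guides_per_gene):
            contents.append(("gene", gene, f"{gene}_g{g+1}"))

    records, raws, truth_rows = [], [], []
    noise = _lognormal_noise(rng, spec.noise_cv, len(contents))
    for i, (ctype, gene, guide) in enumerate(contents):
        row, col = divmod(i, n_cols)
        well = rowcol_to_well(row, col)
        records.append(
            WellRecord(
                plate_id=spec.plate_id,
                well=well,
                row=row,
                col=col,
                content_type=ctype,
                gene_symbol=gene,
                guide_id=guide,
                replicate=spec.replicate,
            )
        )
        if ctype == "blank":
            effect = 0.0
        elif ctype == "mock":
            effect = 1.0
        elif ctype == "scrambled":
            effect = spec.scrambled_effect
        elif ctype == "positive_control":
            effect = spec.positive_effect
        else:
            effect = spec.gene_effects[gene]
        signal = (spec.mock_mean - spec.blank_mean) * effect
        raw = spec.blank_mean + signal * (noise[i] if effect > 0 else 1.0)
        raws.append(raw)
        truth_rows.append(
            {
                "plate_id": spec.plate_id,
                "well": well,
                "content_type": ctype,
                "gene_symbol": gene,
                "guide_id": guide,
                "true_effect": effect,
            }
        )
    readouts = pd.DataFrame(
        {
            "plate_id": spec.plate_id,
            "well": [r.well for r in records],
            "raw_luminescence": raws,
        }
    )
    return records, readouts, pd.DataFrame(truth_rows)


def default_gene_panel(
    n_neutral: int = 40,
    lethal: dict[str, float] | None = None,
) -> dict[str, float]:
    """A 45-gene screen panel: 40 neutral genes plus 5 planted lethal genes
    at 0.2 relative viability, unless overridden."""
    if lethal is None:
        lethal = {f"LETHAL{i+1}": 0.2 for i in range(5)}
    panel = {f"NEUT{i+1:02d}": 1.0 for i in range(n_neutral)}
    panel.update(lethal)
    return panel


def simulate_screen(
    cell_lines: tuple[str, str] = ("lineA", "lineB"),
    shared_lethal: dict[str, float] | None = None,
    specific_lethal: dict[str, dict[str, float]] | None = None,
    n_neutral: int = 40,
    n_replicates: int = 2,
    seed: int = 0,
    **plate_kwargs,
):
    """Two-cell-line screen with shared and line-specific lethal genes.

    Returns ``{cell_line: {"plate_map": [...], "readouts": df,
    "truth": df}}`` with ``n_replicates`` plates per line. Shared lethal
    genes are lethal in both lines; line-specific genes only in theirs;
    every other gene is neutral (effect 1.0).
    """
    if shared_lethal is None:
        shared_lethal = {f"LETHAL{i+1}": 0.2 for i in range(5)}
    if specific_lethal is None:
        specific_lethal = {}
    neutral = {f"NEUT{i+1:02d}": 1.0 for i in range(n_neutral)}
    all_specific = {
        g: e for gmap in specific_lethal.values() for g, e in gmap.items()
    }
    out = {}
    ss = np.random.SeedSequence(seed)
    line_seeds = ss.spawn(len(cell_lines))
    for line, line_ss in zip(cell_lines, line_seeds):
        effects = dict(neutral)
        effects.update(shared_lethal)
        for g in all_specific:
            effects[g] = 1.0
        for g, e in specific_lethal.get(line, {}).items():
            effects[g] = e
        plate_maps, readouts, truths = [], [], []
        rep_seeds = line_ss.spawn(n_replicates)
        for rep, rep_ss in enumerate(rep_seeds, start=1):
            spec = PlateSimSpec(
                gene_effects=effects,
                plate_id=f"{line}_rep{rep}",
                replicate=rep,
                seed=rep_ss.generate_state(1)[0] % (2**31),
                **plate_kwargs,
            )
            pm, ro, tr = simulate_plate(spec)
            plate_maps += pm
            readouts.append(ro)
            tr["cell_line"] = line
            truths.append(tr)
        out[line] = {
            "plate_map": plate_maps,
            "readouts": pd.concat(readouts, ignore_index=True),
            "truth": pd.concat(truths, ignore_index=True),
        }
    return out


@dataclass
class ImageSimSpec:
    """Generative parameters for one synthetic microscopy field."""

    shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 12
    radius_mean: float = 14.0
    radius_sd: float = 2.0
    radius_scale: float = 1.0  # x1.5 emulates an enlarged-nuclei phenotype
    touching_fraction: float = 0.0
    nuclear_intensity: float = 500.0
    signal_model: str = "nuclear_marker"  # or "golgi_puncta"
    signal_level: float = 400.0
    puncta_per_cell: int = 5
    puncta_sigma: float = 2.0
    background: float = 0.0
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    pixel_size: float | None = None
    field_id: str = "field1"
    seed: int = 0


def _render_disk(img: np.ndarray, r0: float, c0: float, radius: float,
                 level: float) -> None:
    """Add an anti-aliased disk: per-pixel coverage ramps linearly over the
    one-pixel boundary band."""
    h, w = img.shape
    rmin = max(int(r0 - radius - 2), 0)
    rmax = min(int(r0 + radius + 3), h)
    cmin = max(int(c0 - radius - 2), 0)
    cmax = min(int(c0 + radius + 3), w)
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dist = np.hypot(rr - r0, cc - c0)
    coverage = np.clip(radius - dist + 0.5, 0.0, 1.0)
    img[rmin:rmax, cmin:cmax] += level * coverage


def _disk_mask(shape, r0, c0, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(rr - r0, cc - c0) < radius


def simulate_image(spec: ImageSimSpec):
    """Render one field: returns (ImageField, truth label map, truth table).

    Nuclei are anti-aliased disks; a ``touching_fraction`` of them are
    placed in pairs at center distance 0.8x the radius sum so the watershed
    split is exercised. In ``golgi_puncta`` mode, Gaussian spots of known
    integrated intensity are scattered in a perinuclear ring around each
    nucleus. Noise (Gaussian and/or Poisson) is applied last; the truth
    table records centers, radii and per-object intensities.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    nuclear = np.zeros((h, w), dtype=float)
    signal = np.zeros((h, w), dtype=float)
    truth_labels = np.zeros((h, w), dtype=np.int32)

    n_pairs = int(round(spec.n_nuclei * spec.touching_fraction / 2))
    n_single = spec.n_nuclei - 2 * n_pairs

    placed: list[tuple[float, float, float]] = []  # (r, c, radius)

    def sample_radius() -> float:
        r = rng.normal(spec.radius_mean, spec.radius_sd) * spec.radius_scale
        return float(np.clip(r, 4.0, min(h, w) / 6))

    def fits(r0, c0, radius, min_gap=6.0) -> bool:
        margin = radius + 3
        if not (margin <= r0 < h - margin and margin <= c0 < w - margin):
            return False
        return all(
            np.hypot(r0 - pr, c0 - pc) >= radius + prad + min_gap
            for pr, pc, prad in placed
        )

    def place_one(radius) -> tuple[float, float]:
        for _ in range(1000):
            r0 = rng.uniform(0, h)
            c0 = rng.uniform(0, w)
            if fits(r0, c0, radius):
                return r0, c0
        raise PlacementError(
            f"could not place nucleus of radius {radius:.1f} in field "
            f"{spec.field_id!r}"
        )

    centers: list[tuple[float, float, float]] = []
    for _ in range(n_pairs):
        r1, r2 = sample_radius(), sample_radius()
        d = 0.8 * (r1 + r2)
        for _ in range(1000):
            rc, cc_ = rng.uniform(0, h), rng.uniform(0, w)
            theta = rng.uniform(0, 2 * math.pi)
            rc2 = rc + d * math.sin(theta)
            cc2 = cc_ + d * math.cos(theta)
            if fits(rc, cc_, r1 + d) and fits(rc2, cc2, r2 + d):
                break
        else:
            raise PlacementError("could not place touching pair")
        centers.append((rc, cc_, r1))
        centers.append((rc2, cc2, r2))
        placed.append((rc, cc_, r1 + d / 2))
        placed.append((rc2, cc2, r2 + d / 2))
    for _ in range(n_single):
        radius = sample_radius()
        r0, c0 = place_one(radius)
        centers.append((r0, c0, radius))
        placed.append((r0, c0, radius))

    truth_rows = []
    dist_stack = np.full((h, w), np.inf)
    for lab, (r0, c0, radius) in enumerate(centers, start=1):
        _render_disk(nuclear, r0, c0, radius, spec.nuclear_intensity)
        mask = _disk_mask((h, w), r0, c0, radius)
        rr, cc = np.ogrid[:h, :w]
        d = np.hypot(rr - r0, cc - c0)
        take = mask & (d < dist_stack)
        truth_labels[take] = lab
        dist_stack = np.where(take, d, dist_stack)
        truth_rows.append(
            {
                "label": lab,
                "center_r": r0,
                "center_c": c0,
                "radius": radius,
                "area_px": int(mask.sum()),
            }
        )
    truth = pd.DataFrame(truth_rows)

    if spec.signal_model == "nuclear_marker":
        for lab, (r0, c0, radius) in enumerate(centers, start=1):
            _render_disk(signal, r0, c0, radius, spec.signal_level)
        truth["signal_total"] = [
            spec.signal_level * a for a in truth["area_px"]
        ]
    elif spec.signal_model == "golgi_puncta":
        totals = []
        per_punctum = spec.signal_level
        for lab, (r0, c0, radius) in enumerate(centers, start=1):
            total = 0.0
            for _ in range(spec.puncta_per_cell):
                ang = rng.uniform(0, 2 * math.pi)
                rad = radius + rng.uniform(3, 8)
                pr = np.clip(r0 + rad * math.sin(ang), 4, h - 5)
                pc = np.clip(c0 + rad * math.cos(ang), 4, w - 5)
                total += _render_gaussian_spot(
                    signal, float(pr), float(pc), spec.puncta_sigma,
                    per_punctum,
                )
            totals.append(total)
        truth["signal_total"] = totals
    else:
        raise ValueError(f"unknown signal model {spec.signal_model!r}")

    nuclear += spec.background
    signal += spec.background
    if spec.poisson_noise:
        nuclear = rng.poisson(np.maximum(nuclear, 0)).astype(float)
        signal = rng.poisson(np.maximum(signal, 0)).astype(float)
    if spec.gaussian_noise_sd > 0:
        nuclear = nuclear + rng.normal(0, spec.gaussian_noise_sd, (h, w))
        signal = signal + rng.normal(0, spec.gaussian_noise_sd, (h, w))
    nuclear = np.maximum(nuclear, 0)
    signal = np.maximum(signal, 0)

    fld = ImageField(
        nuclear_channel=nuclear,
        signal_channel=signal,
        pixel_size=spec.pixel_size,
        field_id=spec.field_id,
    )
    return fld, truth_labels, truth


def _render_gaussian_spot(img, r0, c0, sigma, integrated) -> float:
    """Add a 2-D Gaussian spot with the given integrated intensity; returns
    the intensity actually deposited inside the image bounds."""
    h, w = img.shape
    ext = int(math.ceil(4 * sigma))
    rmin, rmax = max(int(r0) - ext, 0), min(int(r0) + ext + 1, h)
    cmin, cmax = max(int(c0) - ext, 0), min(int(c0) + ext + 1, w)
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    g = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    g *= integrated / (2 * math.pi * sigma**2)
    img[rmin:rmax, cmin:cmax] += g
    return float(g.sum())


def simulate_turnover_table(
    n: int,
    ed_fraction: float = 0.5,
    log10_median_h: float = math.log10(30.0),
    log10_sd: float = 1.0 / math.log(10.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic protein-turnover table with a known intended half-life.

    Half-lives are log-normal (median ``10**log10_median_h`` hours).
    ED rows get ``k = ln2 / t_half``; NED rows get a two-pool mixture
    (alpha, k_fast, k_slow) whose solved half-life equals the intended one:
    alpha and the fast/slow rate ratio are sampled, then ``k_slow`` is
    solved so that the mixture's remaining fraction is 1/2 at the intended
    time. The ``true_half_life_h`` column stores the intent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t_half = 10 ** rng.normal(log10_median_h, log10_sd, size=n)
    is_ed = rng.uniform(size=n) < ed_fraction
    rows = []
    for i in range(n):
        rec = {
            "protein_id": f"P{i+1:05d}",
            "deg_class": "ED" if is_ed[i] else "NED",
            "k": "",
            "alpha": "",
            "k_fast": "",
            "k_slow": "",
            "true_half_life_h": t_half[i],
        }
        if is_ed[i]:
            rec["k"] = LN2 / t_half[i]
        else:
            alpha = rng.uniform(0.3, 0.7)
            ratio = rng.uniform(3.0, 10.0)
            t50 = t_half[i]

            def gap(k_slow, alpha=alpha, ratio=ratio, t50=t50):
                return remaining_fraction(
                    t50, alpha, ratio * k_slow, k_slow
                ) - 0.5

            # R(t50) is decreasing in k_slow; bracket around ln2/t50
            lo, hi = LN2 / t50 / ratio / 10, LN2 / t50 * 10
            k_slow = brentq(gap, lo, hi, xtol=1e-12)
            rec["alpha"] = alpha
            rec["k_fast"] = ratio * k_slow
            rec["k_slow"] = k_slow
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df
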