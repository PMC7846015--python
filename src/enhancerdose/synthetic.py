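"""Synthetic reporter-assay data with known ground truth.

The generator emulates the statistical structure of a transgene reporter
dose-response experiment in *Ciona* embryos so that every downstream stage
can be exercised and validated against known truth:

* **Mosaic electroporation** — each notochord cell expresses the transgene
  (is ON) with probability ``p_on_baseline``, optionally modulated by its
  own Hill curve in log-dose (the "switch" axis of expression loss).
* **Batch efficiency** — one multiplicative log-normal factor per
  electroporation batch scales all of its ON-cell intensities, matching
  the assumption behind DMSO-based batch normalization.
* **Skewed, heteroskedastic intensities** — ON cells draw log-normal
  intensities whose *median* tracks the reporter's true dose-response
  curve (the "fade" axis); the log-scale sd is constant, so the absolute
  spread grows with the mean.
* **Bimodal modal gray values** — OFF cells draw dim background whose ROI
  mode never exceeds ``off_mode_ceiling`` (default 10), ON cells always
  exceed it, reproducing the bimodal mode distribution used for ON/OFF
  classification.
* **Founder-cell sensitivity** — in situ scores use per-founder additive
  shifts of the log10-EC50 (medial cells more resistant by default).

By default the per-reporter ON-fraction Hill is disabled (mosaicism is
dose-independent), so the expected embryo-level expression follows the
configured reporter curve exactly and fitted parameters have well-defined
truth.  Switch-type experiments enable ``on_response`` explicitly.

All outputs are deterministic given ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import BiphasicParams, HillParams, encode_log_dose, eval_biphasic, eval_monophasic
from .imaging import MAX_GRAY, ImageStack

__all__ = [
    "FOUNDER_PAIRS",
    "SCORE_COLUMNS",
    "ReporterTruth",
    "OnResponse",
    "SynthConfig",
    "GroundTruth",
    "ImageStackSpec",
    "ImageGroundTruth",
    "simulate_experiment",
    "simulate_insitu",
    "simulate_image_stack",
]

#: the ten notochord founder blastomeres, in fixed left/right pair order
FOUNDER_PAIRS = ("A8.5", "A8.6", "A8.13", "A8.14", "B8.6")
SCORE_COLUMNS = tuple(f"{p}_{s}" for p in FOUNDER_PAIRS for s in ("L", "R"))


@dataclass(frozen=True)
class ReporterTruth:
    """True dose-response model for one reporter."""

    kind: str  # "monophasic" | "biphasic"
    params: HillParams | BiphasicParams

    def curve(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "monophasic":
            return eval_monophasic(x, self.params)
        if self.kind == "biphasic":
            return eval_biphasic(x, self.params)
        raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass(frozen=True)
class OnResponse:
    """Dose dependence of the ON fraction: a monophasic Hill in log-dose.

    ``p_on(x) = p_on_baseline * (floor + (1 - floor) * logistic)`` with its
    own log10-EC50 and slope; ``floor`` is the fraction of baseline
    mosaicism that survives saturating inhibition.
    """

    ec50_log10: float
    hill: float = -2.0
    floor: float = 0.0

    def fraction(self, x: np.ndarray, p_baseline: float) -> np.ndarray:
        phase = eval_monophasic(x, (1.0, self.hill, self.ec50_log10, 0.0))
        return p_baseline * (self.floor + (1.0 - self.floor) * phase)


def default_truth() -> dict[str, ReporterTruth]:
    """Study-like true curves for the three reporter constructs.

    The distal enhancer is sensitive but shallow (EC50 0.0686 uM, Hill
    -1.43), the proximal enhancer resistant and steep (EC50 0.5 uM, Hill
    -5.0), and the full-length construct biphasic with phases near the two
    single-enhancer EC50s and a middle plateau around 0.63.  Amplitudes
    are on the normalized-expression scale where the full-length DMSO mean
    is 1; proximal + distal tops sum to slightly below 1 (weak synergy of
    the combined construct).
    """
    return {
        "Proximal": ReporterTruth(
            "monophasic", HillParams(A=0.62, B=-5.0, C=np.log10(0.5), D=0.02)
        ),
        "Distal": ReporterTruth(
            "monophasic", HillParams(A=0.30, B=-1.43, C=np.log10(0.0686), D=0.065)
        ),
        "FullLength": ReporterTruth(
            "biphasic",
            BiphasicParams(
                A=1.0, B=-3.0, C=np.log10(0.05), D=0.63, E=-5.0, F=np.log10(0.63), G=0.02
            ),
        ),
    }


def default_founder_offsets() -> dict[str, float]:
    """log10-EC50 shifts per founder pair: medial cells more resistant."""
    return {"A8.5": 0.15, "A8.6": 0.10, "A8.13": 0.0, "A8.14": 0.0, "B8.6": 0.0}


@dataclass
class SynthConfig:
    """Configuration of a synthetic reporter dose-response experiment.

    Defaults reflect the study design this generator emulates: three
    independent electroporation batches, ~10 embryos per batch per dose,
    nine dose levels (DMSO vehicle encoded as 0 uM plus eight U0126 doses
    spanning 0.029-4 uM), three reporter constructs, and 40 notochord
    cells per embryo (32 primary + 8 secondary).
    """

    n_batches: int = 3
    embryos_per_batch_per_dose: int = 10
    doses: tuple = (0.0, 0.029, 0.05, 0.1, 0.18, 0.34, 0.63, 1.0, 4.0)
    reporters: tuple = ("Proximal", "Distal", "FullLength")
    true_params: dict = field(default_factory=default_truth)
    batch_efficiency_sd: float = 0.25  # sd of ln batch factor
    p_on_baseline: float = 0.7
    on_response: dict = field(default_factory=dict)  # reporter -> OnResponse | None
    on_intensity_shape: float = 0.6  # log-scale sd of ON-cell intensity
    off_mode_ceiling: int = 10
    intensity_scale: float = 1200.0  # ON-cell mean gray value at expression 1
    off_background_mean: float = 5.0
    roi_area_px: int = 80  # pixels in a 10-px-diameter ROI disk
    ectopic_fraction: float = 0.0  # embryo-level non-notochord signal
    founder_offsets: dict = field(default_factory=default_founder_offsets)
    insitu_doses: tuple = (0.0, 0.0625, 0.125, 0.25, 0.5, 1.0)
    insitu_embryos_per_dose: int = 75
    insitu_ec50_log10: float = float(np.log10(0.6))
    insitu_hill: float = -1.8
    insitu_noise_sd: float = 0.4
    n_notochord_cells: int = 40
    seed: int = 0

    def validate(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if doses.size == 0:
            raise ValueError("dose list is empty")
        if np.any(doses < 0):
            raise ValueError("doses must be nonnegative")
        if (doses == 0).sum() != 1:
            raise ValueError("exactly one DMSO (0 uM) level is required")
        if not 0.0 <= self.p_on_baseline <= 1.0:
            raise ValueError("p_on_baseline must be in [0, 1]")
        if self.n_notochord_cells <= 0:
            raise ValueError("n_notochord_cells must be > 0")
        if len(self.reporters) == 0:
            raise ValueError("at least one reporter is required")
        for rep in self.reporters:
            if rep not in self.true_params:
                raise ValueError(f"unknown reporter {rep!r}: no true parameters given")

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Per-record truth for a simulated experiment."""

    embryos: pd.DataFrame  # embryo_id, batch_factor, true_total, expected_total
    cells: pd.DataFrame  # embryo_id, cell_index, true_on, true_mean
    true_params: dict  # reporter -> ReporterTruth


def _lineages(n_cells: int) -> np.ndarray:
    """First 32 of 40 cells are primary (A-lineage), last 8 secondary."""
    if n_cells == 40:
        n_primary = 32
    else:
        n_primary = int(round(0.8 * n_cells))
    return np.array(["primary"] * n_primary + ["secondary"] * (n_cells - n_primary))


def simulate_experiment(
    config: SynthConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate embryo and cell tables for every batch x dose x reporter.

    Returns ``(embryos, cells, truth)``.  The embryo table holds one row
    per embryo with its raw summed enhancer value (``sev``); the cell
    table one row per notochord cell with ROI summary statistics.  SEV is
    the sum of per-cell ROI totals plus an optional ectopic term
    (``ectopic_fraction`` of the ON-cell signal) that is *not* present in
    the cell table, mimicking non-notochord reporter signal picked up by
    whole-embryo masks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    doses = np.asarray(config.doses, dtype=float)
    x = encode_log_dose(doses, doses == 0)
    n_cells = config.n_notochord_cells
    n_emb = config.embryos_per_batch_per_dose
    lineage = _lineages(n_cells)

    batch_factor = rng.lognormal(mean=0.0, sigma=config.batch_efficiency_sd, size=config.n_batches)
    if config.batch_efficiency_sd == 0:
        batch_factor = np.ones(config.n_batches)

    emb_rows = []
    cell_frames = []
    truth_emb = []
    truth_cells = []

    for rep in config.reporters:
        truth = config.true_params[rep]
        g = truth.curve(x)  # expected expression per dose (normalized scale)
        on_resp = config.on_response.get(rep)
        if on_resp is None:
            p_on = np.full_like(x, config.p_on_baseline)
        else:
            p_on = on_resp.fraction(x, config.p_on_baseline)
        for bi in range(config.n_batches):
            bf = batch_factor[bi]
            for di, dose in enumerate(doses):
                median_on = config.intensity_scale * g[di] * bf
                for ei in range(n_emb):
                    embryo_id = f"{rep}_b{bi + 1}_d{di}_e{ei + 1}"
                    on = rng.random(n_cells) < p_on[di]
                    noise = (
                        np.exp(rng.normal(0.0, config.on_intensity_shape, size=n_cells))
                        if config.on_intensity_shape > 0
                        else np.ones(n_cells)
                    )
                    mean_val = np.where(
                        on, median_on * noise, config.off_background_mean * noise
                    )
                    mode = np.where(
                        on,
                        np.clip(np.rint(0.8 * mean_val), config.off_mode_ceiling + 1, MAX_GRAY),
                        np.clip(np.rint(0.8 * mean_val), 0, config.off_mode_ceiling),
                    ).astype(int)
                    total = mean_val * config.roi_area_px
                    notochord_sum = total.sum()
                    ectopic = config.ectopic_fraction * total[on].sum()
                    sev = notochord_sum + ectopic
                    expected = n_cells * config.roi_area_px * (
                        p_on[di] * median_on + (1 - p_on[di]) * config.off_background_mean
                    ) * np.exp(0.5 * config.on_intensity_shape**2)
                    emb_rows.append(
                        (embryo_id, rep, dose, dose == 0.0, f"batch{bi + 1}", sev)
                    )
                    truth_emb.append((embryo_id, bf, notochord_sum, float(expected)))
                    cell_frames.append(
                        pd.DataFrame(
                            {
                                "embryo_id": embryo_id,
                                "batch_id": f"batch{bi + 1}",
                                "reporter": rep,
                                "dose_um": dose,
                                "vehicle": dose == 0.0,
                                "cell_index": np.arange(1, n_cells + 1),
                                "lineage": lineage,
                                "roi_mean": mean_val,
                                "roi_sd": 0.3 * mean_val,
                                "roi_mode": mode,
                                "roi_max": 1.8 * mean_val,
                                "roi_min": 0.3 * mean_val,
                                "roi_median": 0.95 * mean_val,
                                "roi_total": total,
                            }
                        )
                    )
                    truth_cells.append(
                        pd.DataFrame(
                            {
                                "embryo_id": embryo_id,
                                "cell_index": np.arange(1, n_cells + 1),
                                "true_on": on,
                                "true_mean": mean_val,
                            }
                        )
                    )

    embryos = pd.DataFrame(
        emb_rows, columns=["embryo_id", "reporter", "dose_um", "vehicle", "batch_id", "sev"]
    )
    cells = pd.concat(cell_frames, ignore_index=True)
    truth = GroundTruth(
        embryos=pd.DataFrame(
            truth_emb, columns=["embryo_id", "batch_factor", "true_total", "expected_total"]
        ),
        cells=pd.concat(truth_cells, ignore_index=True),
        true_params=dict(config.true_params),
    )
    return embryos, cells, truth


def simulate_insitu(config: SynthConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate semi-quantitative in situ score matrices.

    Each embryo contributes ten integer scores (0-3), one per founder
    blastomere.  The latent per-cell expression is ``3 x`` a monophasic
    Hill in log-dose whose log10-EC50 is shifted by the founder pair's
    offset, plus Gaussian noise, discretized at fixed thresholds
    0.5 / 1.5 / 2.5.
    """
    config.validate()
    missing = [p for p in FOUNDER_PAIRS if p not in config.founder_offsets]
    if missing:
        raise ValueError(f"founder_offsets missing pairs: {missing}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    doses = np.asarray(config.insitu_doses, dtype=float)
    x = encode_log_dose(doses, doses == 0)
    offsets = np.array([config.founder_offsets[c.rsplit("_", 1)[0]] for c in SCORE_COLUMNS])

    rows = []
    n = config.insitu_embryos_per_dose
    for di, dose in enumerate(doses):
        latent_mean = 3.0 * np.array(
            [
                eval_monophasic(
                    x[di], (1.0, config.insitu_hill, config.insitu_ec50_log10 + off, 0.0)
                )
                for off in offsets
            ]
        )
        for ei in range(n):
            noise = (
                rng.normal(0.0, config.insitu_noise_sd, size=len(SCORE_COLUMNS))
                if config.insitu_noise_sd > 0
                else np.zeros(len(SCORE_COLUMNS))
            )
            scores = np.digitize(latent_mean + noise, [0.5, 1.5, 2.5])
            batch = f"batch{ei % config.n_batches + 1}"
            rows.append([f"is_d{di}_e{ei + 1}", dose, dose == 0.0, batch, *scores])

    return pd.DataFrame(
        rows, columns=["embryo_id", "dose_um", "vehicle", "batch_id", *SCORE_COLUMNS]
    )


# ----------------------------------------------------------------------
# image stacks
# ----------------------------------------------------------------------

@dataclass
class ImageStackSpec:
    """Geometry and noise of one synthetic two-channel stack."""

    shape: tuple = (12, 96, 128)  # (z, y, x), kept small on purpose
    background: float = 20.0
    noise_sd: float = 4.0
    phalloidin_level: float = 1500.0
    n_blobs: int = 25
    blob_sigma: float = 1.6  # voxels
    blob_signal_mean: float = 2.0e4  # integrated gray per blob
    centers: list | None = None  # explicit (z, y, x) blob centers
    signals: list | None = None  # explicit per-blob integrated signals


@dataclass
class ImageGroundTruth:
    """Planted truth for a synthetic stack."""

    blob_centers: np.ndarray
    blob_signals: np.ndarray
    total_signal: float
    background: float
    embryo_mask_2d: np.ndarray


def _ellipsoid_mask(shape) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = [(s - 1) / 2.0 for s in shape]
    rz, ry, rx = [0.42 * s for s in shape]
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def simulate_image_stack(
    config: SynthConfig, spec: ImageStackSpec | None = None, seed: int | None = None
) -> tuple[ImageStack, ImageGroundTruth]:
    """Render a small two-channel stack with known planted reporter signal.

    The phalloidin channel holds one bright ellipsoidal embryo body; the
    reporter channel holds Gaussian blobs (integrated signal known per
    blob) over a flat background plus Gaussian noise.  Voxels are rounded
    and clipped to the 12-bit range.
    """
    spec = spec or ImageStackSpec()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = tuple(spec.shape)
    body = _ellipsoid_mask(shape)

    if spec.centers is not None:
        centers = np.asarray(spec.centers, dtype=float)
    else:
        idx = np.argwhere(body)
        pick = rng.choice(idx.shape[0], size=spec.n_blobs, replace=False)
        centers = idx[pick].astype(float)
    if centers.size and (
        np.any(centers < 0) or np.any(centers >= np.asarray(shape))
    ):
        raise ValueError("blob centers outside stack bounds")
    if spec.signals is not None:
        signals = np.asarray(spec.signals, dtype=float)
        if signals.shape[0] != centers.shape[0]:
            raise ValueError("signals and centers length mismatch")
    else:
        signals = spec.blob_signal_mean * rng.lognormal(0.0, 0.4, size=centers.shape[0])

    reporter = np.zeros(shape, dtype=float)
    half = max(2, int(np.ceil(4 * spec.blob_sigma)))
    for (cz, cy, cx), s in zip(centers, signals):
        z0, z1 = max(0, int(cz) - half), min(shape[0], int(cz) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(shape[1], int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(shape[2], int(cx) + half + 1)
        zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
        kern = np.exp(
            -((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spec.blob_sigma**2)
        )
        # normalize over the rendered support so the planted sum is exactly s
        reporter[z0:z1, y0:y1, x0:x1] += s * kern / kern.sum()

    reporter += spec.background
    if spec.noise_sd > 0:
        reporter += rng.normal(0.0, spec.noise_sd, size=shape)
    reporter = np.clip(np.rint(reporter), 0, MAX_GRAY).astype(np.uint16)

    phal = np.where(body, spec.phalloidin_level, 0.0)
    if spec.noise_sd > 0:
        phal = phal + rng.normal(0.0, spec.noise_sd, size=shape)
    phal = np.clip(np.rint(phal), 0, MAX_GRAY).astype(np.uint16)

    truth = ImageGroundTruth(
        blob_centers=centers,
        blob_signals=signals,
        total_signal=float(signals.sum()),
        background=spec.background,
        embryo_mask_2d=body.any(axis=0),
    )
    return ImageStack(phal, reporter), truth
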