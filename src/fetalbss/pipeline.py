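"""End-to-end extraction pipeline and channel-combination enumeration.

The pipeline mirrors the block structure of the extraction experiment:
bandpass preprocessing → centering (+ whitening for ICA) → blind source
separation (ICA, PCA or both) → role labeling → adaptive lag/amplitude
compensation and maternal subtraction → fetal R-peak detection → fHR
series → optional scoring against a reference annotation set and quality /
T/QRS reports.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .compensation import CompensationParams, compensate_and_subtract
from .evaluation import bland_altman, detection_metrics, match_beats
from .ica import RoleAssignment, fit_ica, resolve_ambiguity
from .io_formats import AnnotationSet, MultichannelRecord, write_annotations, write_record
from .pca import estimate_principal_axes
from .preprocess import bandpass_filter, center, whiten
from .qrs import detect_r_peaks_cwt, detect_r_peaks_pt, fhr_series
from .quality import compute_quality
from .stan import t_qrs_ratio

__all__ = ["PipelineConfig", "SeparationResult", "extract_fecg",
           "run_pipeline", "enumerate_channel_subsets"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    method: str = "both"                     # ica | pca | both
    channel_subset: list[int] = field(default_factory=lambda: [0, 1, 2, 3])
    seed: int = 0
    bandpass_low_hz: float = 3.0
    bandpass_high_hz: float = 150.0
    bandpass_order: int | None = None
    ica_tol: float = 1e-6
    ica_max_iter: int = 500
    maternal_band_bpm: tuple[float, float] = (50.0, 110.0)
    fetal_band_bpm: tuple[float, float] = (110.0, 220.0)
    comp_max_lag_ms: float = 50.0
    comp_window_s: float = 2.0
    comp_gain_bounds: tuple[float, float] = (0.0, 10.0)
    detector: str = "pt"                     # pt | cwt
    match_tolerance_ms: float = 50.0
    maf_window: int = 10
    stan_n_beats: int = 30
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("ica", "pca", "both"):
            raise ValueError(f"invalid method {self.method!r}")
        if len(self.channel_subset) < 2:
            raise ValueError("blind source separation needs >= 2 channels")
        if self.detector not in ("pt", "cwt"):
            raise ValueError(f"invalid detector {self.detector!r}")


@dataclass
class SeparationResult:
    method: str
    unmixing: np.ndarray          # components = unmixing @ centered channels
    components: np.ndarray
    roles: RoleAssignment
    maternal_estimate: np.ndarray  # compensated (aligned+scaled) mECG*
    fecg: np.ndarray


def _compensated(roles: RoleAssignment, cfg: PipelineConfig, fs: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    fetal = roles.fetal
    maternal = roles.maternal
    if fetal is None:
        raise RuntimeError("no fetal-enhanced component identified")
    if maternal is None:
        log.warning("no maternal-dominant component; skipping subtraction")
        return fetal, np.zeros_like(fetal)
    params = CompensationParams(max_lag_ms=cfg.comp_max_lag_ms,
                                window_s=cfg.comp_window_s,
                                gain_bounds=cfg.comp_gain_bounds)
    fecg = compensate_and_subtract(fetal, maternal, params, fs)
    return fecg, fetal - fecg


def extract_fecg(record: MultichannelRecord, method: str,
                 cfg: PipelineConfig | None = None) -> SeparationResult:
    """Run one separation method on the configured channel subset."""
    cfg = cfg or PipelineConfig(method=method)
    fs = record.fs
    sub = record.signals[cfg.channel_subset]
    filtered = bandpass_filter(
        MultichannelRecord(sub, fs), cfg.bandpass_low_hz,
        cfg.bandpass_high_hz, cfg.bandpass_order).signals
    xc, _ = center(filtered)
    if method == "ica":
        white = whiten(xc, reduce=True)
        result = fit_ica(white.xw, seed=cfg.seed, tol=cfg.ica_tol,
                         max_iter=cfg.ica_max_iter)
        components = result.y
        unmixing = result.W @ white.K
    elif method == "pca":
        pres = estimate_principal_axes(xc)
        components = pres.s
        unmixing = pres.U.T
    else:
        raise ValueError(f"extract_fecg handles one method at a time, got {method!r}")
    roles = resolve_ambiguity(components, sub, fs,
                              maternal_band_bpm=cfg.maternal_band_bpm,
                              fetal_band_bpm=cfg.fetal_band_bpm)
    fecg, maternal_est = _compensated(roles, cfg, fs)
    return SeparationResult(method=method, unmixing=unmixing,
                            components=roles.components, roles=roles,
                            maternal_estimate=maternal_est, fecg=fecg)


def _detect(signal: np.ndarray, fs: float, cfg: PipelineConfig) -> AnnotationSet:
    detect = detect_r_peaks_pt if cfg.detector == "pt" else detect_r_peaks_cwt
    return detect(signal, fs, mode="fetal")


def run_pipeline(record: MultichannelRecord, cfg: PipelineConfig,
                 reference: AnnotationSet | None = None,
                 maternal_reference: AnnotationSet | None = None) -> dict:
    """Full extraction + evaluation; returns a JSON-serializable report.

    ``reference`` are gold-standard fetal R peaks (e.g. from a scalp
    electrode or synthetic truth); when present, detection statistics,
    Bland–Altman agreement and T/QRS comparison are computed.  When
    ``maternal_reference`` is also given, the abdominal quality indices
    are reported for the first configured channel.
    """
    methods = ["ica", "pca"] if cfg.method == "both" else [cfg.method]
    fs = record.fs
    report: dict = {"config": {k: v for k, v in asdict(cfg).items()},
                    "fs": fs, "version": __version__}
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    ref_fhr = None
    if reference is not None and len(reference) >= 2:
        ref_fhr = fhr_series(reference, fs, cfg.maf_window)

    if maternal_reference is not None and reference is not None:
        q = compute_quality(record.signals[cfg.channel_subset[0]],
                            maternal_reference, reference, fs)
        report["quality"] = {k: (float(v) if np.isscalar(v) else v)
                             for k, v in asdict(q).items()}

    for method in methods:
        sep = extract_fecg(record, method, cfg)
        detected = _detect(sep.fecg, fs, cfg)
        entry: dict = {"n_detected": len(detected),
                       "roles": sep.roles.roles,
                       "rates_bpm": [float(r) for r in sep.roles.rates_bpm]}
        if len(detected) >= 2:
            fhr = fhr_series(detected, fs, cfg.maf_window)
            entry["mean_fhr_bpm"] = float(np.mean(fhr.bpm))
        if reference is not None:
            m = match_beats(detected, reference, cfg.match_tolerance_ms, fs)
            se, ppv, acc, f1 = detection_metrics(m.TP, m.FP, m.FN)
            entry["detection"] = {"TP": m.TP, "FP": m.FP, "FN": m.FN,
                                  "Se": se, "PPV": ppv, "ACC": acc, "F1": f1}
            if ref_fhr is not None and len(detected) >= 2:
                ba = bland_altman(fhr, ref_fhr)
                entry["bland_altman"] = asdict(ba)
        try:
            st = t_qrs_ratio(sep.fecg, detected, fs, n_beats=cfg.stan_n_beats)
            entry["stan"] = asdict(st)
        except ValueError as exc:
            entry["stan"] = {"error": str(exc)}
        report[method] = entry
        if outdir:
            write_record(MultichannelRecord(sep.fecg[None, :], fs,
                                            [f"fecg_{method}"]),
                         outdir / f"fecg_{method}.csv")
            write_annotations(detected, outdir / f"fetal_peaks_{method}.txt")
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


def enumerate_channel_subsets(n_channels: int = 4, min_size: int = 2
                              ) -> list[tuple[int, ...]]:
    """All channel subsets of size >= min_size, lexicographic order.

    Four abdominal channels give the 11 testable electrode combinations
    (6 pairs + 4 triples + 1 full set).
    """
    if n_channels < min_size:
        raise ValueError("n_channels must be >= min_size")
    subsets: list[tuple[int, ...]] = []
    for size in range(min_size, n_channels + 1):
        subsets.extend(itertools.combinations(range(n_channels), size))
    return subsets
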