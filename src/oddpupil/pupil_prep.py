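"""Pupil preprocessing: raw two-eye samples to per-trial BPS/SEPR features.

The chain, applied per trial and per eye where applicable:

1. range filter        — diameters < 2 mm or > 8 mm marked invalid
2. dilation-speed MAD  — speed outliers (> median + 3*MAD) removed, twice
3. blink detection     — invalid runs of 75-250 ms labelled blinks; 27 ms
                         of surrounding samples discarded
4. gap interpolation   — invalid runs up to 300 ms linearly imputed
5. eye averaging       — mean of available eyes per sample
6. baseline correction — subtract the mean over the first 250 ms
                         post-onset (baseline pupil size, BPS)
7. SEPR                — mean corrected diameter over 500-1500 ms
8. validity            — trials with < 50% usable samples excluded

Eyes are filtered independently and averaged afterwards; imputed samples
count as usable.  All windows are half-open ``[a, b)`` in ms relative to
stimulus onset at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrialUnusableError(ValueError):
    """Raised when a trial has no usable baseline samples."""


@dataclass
class PrepConfig:
    """Knobs of the preprocessing chain (defaults follow the pipeline spec)."""

    range_mm: tuple[float, float] = (2.0, 8.0)
    mad_k: float = 3.0
    mad_passes: int = 2
    speed_method: str = "both"  # "both" (max of back/forward) or "forward"
    threshold_form: str = "median_plus_k_mad"  # or "k_mad"
    mad_constant: float = 1.0  # 1.4826 for normal-consistent MAD
    blink_range_ms: tuple[float, float] = (75.0, 250.0)
    blink_pad_ms: float = 27.0
    max_gap_ms: float = 300.0
    baseline_window_ms: tuple[float, float] = (0.0, 250.0)
    sepr_window_ms: tuple[float, float] = (500.0, 1500.0)
    min_valid_fraction: float = 0.5


@dataclass
class PupilSeries:
    """One trial of two-eye pupil samples.

    ``t`` is in ms relative to stimulus onset and must be strictly
    increasing.  ``valid_*`` flags track rejection; ``imputed_*`` flags
    mark interpolated samples (which count as usable downstream).
    """

    t: np.ndarray
    left_mm: np.ndarray
    right_mm: np.ndarray
    valid_l: np.ndarray
    valid_r: np.ndarray
    imputed_l: np.ndarray = None  # type: ignore[assignment]
    imputed_r: np.ndarray = None  # type: ignore[assignment]
    blink_l: np.ndarray = None  # type: ignore[assignment]
    blink_r: np.ndarray = None  # type: ignore[assignment]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) == 0:
            raise ValueError("t must be a non-empty 1-d array")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        n = len(self.t)
        self.left_mm = np.asarray(self.left_mm, dtype=float)
        self.right_mm = np.asarray(self.right_mm, dtype=float)
        self.valid_l = np.asarray(self.valid_l, dtype=bool)
        self.valid_r = np.asarray(self.valid_r, dtype=bool)
        for name in ("imputed_l", "imputed_r", "blink_l", "blink_r"):
            v = getattr(self, name)
            setattr(
                self,
                name,
                np.zeros(n, dtype=bool) if v is None else np.asarray(v, bool),
            )
        for name in (
            "left_mm", "right_mm", "valid_l", "valid_r",
            "imputed_l", "imputed_r", "blink_l", "blink_r",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch with t")

    def copy(self) -> "PupilSeries":
        return PupilSeries(
            t=self.t.copy(),
            left_mm=self.left_mm.copy(),
            right_mm=self.right_mm.copy(),
            valid_l=self.valid_l.copy(),
            valid_r=self.valid_r.copy(),
            imputed_l=self.imputed_l.copy(),
            imputed_r=self.imputed_r.copy(),
            blink_l=self.blink_l.copy(),
            blink_r=self.blink_r.copy(),
            warnings=list(self.warnings),
        )

    @property
    def usable_l(self) -> np.ndarray:
        return self.valid_l | self.imputed_l

    @property
    def usable_r(self) -> np.ndarray:
        return self.valid_r | self.imputed_r

    @property
    def dt_ms(self) -> float:
        if len(self.t) < 2:
            return float("nan")
        return float(np.median(np.diff(self.t)))

    def eyes(self):
        """Iterate ``(value array, valid array, imputed array, suffix)``."""
        yield self.left_mm, self.valid_l, self.imputed_l, "l"
        yield self.right_mm, self.valid_r, self.imputed_r, "r"


@dataclass
class MonoSeries:
    """Single (eye-averaged) pupil series."""

    t: np.ndarray
    value_mm: np.ndarray
    usable: np.ndarray


@dataclass
class TrialPupilFeatures:
    bps: float
    sepr: float
    valid_fraction: float
    included: bool
    n_blinks: int = 0


# ---------------------------------------------------------------------------
# filter stages
# ---------------------------------------------------------------------------

def range_filter(
    series: PupilSeries, lo_mm: float = 2.0, hi_mm: float = 8.0
) -> PupilSeries:
    """Mark samples with implausible diameters (< lo, > hi, non-finite) invalid."""
    out = series.copy()
    for vals, valid, _imp, suffix in out.eyes():
        bad = ~np.isfinite(vals) | (vals < lo_mm) | (vals > hi_mm)
        valid &= ~bad
    return out


def _dilation_speeds(x: np.ndarray, t: np.ndarray, method: str) -> np.ndarray:
    """Per-sample dilation speed over consecutive valid samples.

    ``method="both"`` assigns each sample the larger of its backward and
    forward absolute speed (edge samples use the single available one);
    ``"forward"`` uses the forward speed (last sample falls back on its
    backward speed).
    """
    fwd = np.abs(np.diff(x)) / np.diff(t)
    d = np.empty(len(x), dtype=float)
    if method == "both":
        d[0] = fwd[0]
        d[-1] = fwd[-1]
        if len(x) > 2:
            d[1:-1] = np.maximum(fwd[:-1], fwd[1:])
    elif method == "forward":
        d[:-1] = fwd
        d[-1] = fwd[-1]
    else:
        raise ValueError(f"unknown speed method {method!r}")
    return d


def _mad_threshold(
    d: np.ndarray, k: float, form: str, constant: float
) -> float:
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med))) * constant
    if form == "median_plus_k_mad":
        return med + k * mad
    if form == "k_mad":
        return k * mad
    raise ValueError(f"unknown threshold form {form!r}")


def dilation_speed_filter(
    series: PupilSeries,
    k: float = 3.0,
    passes: int = 2,
    *,
    speed_method: str = "both",
    threshold_form: str = "median_plus_k_mad",
    mad_constant: float = 1.0,
) -> PupilSeries:
    """Remove dilation-speed outliers per eye; repeated on the survivors.

    Each pass recomputes speeds over the currently valid samples (the
    "new trend line") and invalidates samples whose speed exceeds the
    MAD-based threshold.
    """
    out = series.copy()
    for vals, valid, _imp, suffix in out.eyes():
        for _ in range(passes):
            idx = np.flatnonzero(valid)
            if len(idx) < 3:
                out.warnings.append(
                    f"dilation_speed_filter: <3 valid samples (eye {suffix}),"
                    " left unchanged"
                )
                break
            d = _dilation_speeds(vals[idx], out.t[idx], speed_method)
            thr = _mad_threshold(d, k, threshold_form, mad_constant)
            flag = d > thr
            if not flag.any():
                break
            valid[idx[flag]] = False
    return out


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of invalid samples as (start, stop) index pairs,
    stop exclusive."""
    runs = []
    inval = ~valid
    boundaries = np.flatnonzero(np.diff(inval.astype(np.int8)))
    starts = list(boundaries[inval[boundaries + 1]] + 1)
    stops = list(boundaries[~inval[boundaries + 1]] + 1)
    if inval[0]:
        starts.insert(0, 0)
    if inval[-1]:
        stops.append(len(valid))
    for a, b in zip(starts, stops):
        runs.append((int(a), int(b)))
    return runs


def _blink_detect_eye(
    t: np.ndarray,
    valid: np.ndarray,
    blink: np.ndarray,
    dt: float,
    dur_range_ms: tuple[float, float],
    pad_ms: float,
) -> int:
    """In-place blink labelling and padding for one eye; returns run count."""
    if valid.all():
        return 0
    lo, hi = dur_range_ms
    pad_mask = np.zeros(len(valid), dtype=bool)
    n_runs = 0
    for a, b in _invalid_runs(valid):
        dur = t[b - 1] - t[a] + dt
        if not (lo <= dur <= hi):
            continue
        blink[a:b] = True
        n_runs += 1
        t_start, t_end = t[a], t[b - 1]
        pad_mask |= (t >= t_start - pad_ms) & (t < t_start)
        pad_mask |= (t > t_end) & (t <= t_end + pad_ms)
    valid &= ~pad_mask
    return n_runs


def detect_blinks(
    series: PupilSeries,
    dur_range_ms: tuple[float, float] = (75.0, 250.0),
    pad_ms: float = 27.0,
) -> PupilSeries:
    """Label invalid runs of blink-like duration and pad around them.

    A run of invalid samples whose duration (span plus one nominal
    sample period) lies within ``dur_range_ms`` is labelled a blink, and
    every valid sample within ``pad_ms`` of either run edge is discarded.
    """
    out = series.copy()
    dt = out.dt_ms
    for _vals, valid, _imp, suffix in out.eyes():
        blink = out.blink_l if suffix == "l" else out.blink_r
        _blink_detect_eye(out.t, valid, blink, dt, dur_range_ms, pad_ms)
    return out


def _interpolate_eye(
    t: np.ndarray,
    vals: np.ndarray,
    valid: np.ndarray,
    imputed: np.ndarray,
    dt: float,
    max_gap_ms: float,
) -> None:
    """In-place linear imputation of short interior gaps for one eye."""
    if valid.all():
        return
    for a, b in _invalid_runs(valid):
        if a == 0 or b == len(valid):
            continue  # no anchor on one side
        dur = t[b - 1] - t[a] + dt
        if dur > max_gap_ms:
            continue
        ta, xa = t[a - 1], vals[a - 1]
        tb, xb = t[b], vals[b]
        vals[a:b] = np.interp(t[a:b], [ta, tb], [xa, xb])
        imputed[a:b] = True


def interpolate_gaps(series: PupilSeries, max_gap_ms: float = 300.0) -> PupilSeries:
    """Linearly impute interior invalid runs of duration <= ``max_gap_ms``.

    Imputed samples are flagged but not re-marked valid; downstream
    stages treat ``valid | imputed`` as usable.  Runs touching the series
    edges have no anchor on one side and are left missing.
    """
    out = series.copy()
    dt = out.dt_ms
    for vals, valid, imputed, _suffix in out.eyes():
        _interpolate_eye(out.t, vals, valid, imputed, dt, max_gap_ms)
    return out


def average_eyes(series: PupilSeries) -> MonoSeries:
    """Per-sample mean of the usable eyes (single-eye fallback)."""
    ul, ur = series.usable_l, series.usable_r
    lv = np.where(ul, series.left_mm, np.nan)
    rv = np.where(ur, series.right_mm, np.nan)
    both = ul & ur
    value = np.where(both, 0.5 * (lv + rv), np.where(ul, lv, rv))
    return MonoSeries(t=series.t.copy(), value_mm=value, usable=ul | ur)


def baseline_correct(
    mono: MonoSeries, window_ms: tuple[float, float] = (0.0, 250.0)
) -> tuple[MonoSeries, float]:
    """Subtract the baseline pupil size (mean over ``window_ms``).

    Returns the corrected series and the BPS.  Raises
    :class:`TrialUnusableError` if no usable sample falls in the window.
    """
    mask = mono.usable & (mono.t >= window_ms[0]) & (mono.t < window_ms[1])
    if not mask.any():
        raise TrialUnusableError("no usable samples in baseline window")
    bps = float(np.mean(mono.value_mm[mask]))
    corrected = MonoSeries(
        t=mono.t.copy(), value_mm=mono.value_mm - bps, usable=mono.usable.copy()
    )
    return corrected, bps


def compute_sepr(
    corrected: MonoSeries, window_ms: tuple[float, float] = (500.0, 1500.0)
) -> float:
    """Mean baseline-corrected diameter over the response window (NaN if empty)."""
    mask = (
        corrected.usable
        & (corrected.t >= window_ms[0])
        & (corrected.t < window_ms[1])
    )
    if not mask.any():
        return float("nan")
    return float(np.mean(corrected.value_mm[mask]))


def trial_validity(
    mono: MonoSeries, min_valid_fraction: float = 0.5
) -> tuple[float, bool]:
    """Fraction of usable samples (imputed count as usable) and inclusion flag."""
    frac = float(np.mean(mono.usable))
    return frac, bool(frac >= min_valid_fraction)


def preprocess_trial(
    series: PupilSeries, config: PrepConfig | None = None
) -> TrialPupilFeatures:
    """Run the full preprocessing chain on one trial."""
    cfg = config or PrepConfig()
    s = range_filter(series, *cfg.range_mm)
    s = dilation_speed_filter(
        s,
        k=cfg.mad_k,
        passes=cfg.mad_passes,
        speed_method=cfg.speed_method,
        threshold_form=cfg.threshold_form,
        mad_constant=cfg.mad_constant,
    )
    s = detect_blinks(s, cfg.blink_range_ms, cfg.blink_pad_ms)
    s = interpolate_gaps(s, cfg.max_gap_ms)
    n_blinks = len(_blink_runs(s.blink_l)) + len(_blink_runs(s.blink_r))
    mono = average_eyes(s)
    frac, included = trial_validity(mono, cfg.min_valid_fraction)
    try:
        corrected, bps = baseline_correct(mono, cfg.baseline_window_ms)
    except TrialUnusableError:
        return TrialPupilFeatures(
            bps=float("nan"),
            sepr=float("nan"),
            valid_fraction=frac,
            included=False,
            n_blinks=n_blinks,
        )
    sepr = compute_sepr(corrected, cfg.sepr_window_ms) if included else float("nan")
    return TrialPupilFeatures(
        bps=bps,
        sepr=sepr,
        valid_fraction=frac,
        included=included,
        n_blinks=n_blinks,
    )


def _blink_runs(blink: np.ndarray) -> list[tuple[int, int]]:
    if not blink.any():
        return []
    return _invalid_runs(~blink)


# ---------------------------------------------------------------------------
# batched preprocessing (vectorized across trials; equivalent to the
# per-trial chain and tested as such)
# ---------------------------------------------------------------------------

def _row_median_masked(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Median per row over masked entries (NaN for empty rows)."""
    big = np.where(mask, x, np.inf)
    s = np.sort(big, axis=1)
    cnt = mask.sum(axis=1)
    rows = np.arange(x.shape[0])
    lo = np.clip((cnt - 1) // 2, 0, x.shape[1] - 1)
    hi = np.clip(cnt // 2, 0, x.shape[1] - 1)
    med = 0.5 * (s[rows, lo] + s[rows, hi])
    return np.where(cnt > 0, med, np.nan)


def _run_table(seg_valid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invalid runs of a (trials x samples) validity matrix.

    Returns (row, col_start, col_end) per run; runs never cross rows.
    """
    inval = ~seg_valid
    n, m = inval.shape
    prev = np.zeros_like(inval)
    prev[:, 1:] = inval[:, :-1]
    start = inval & ~prev
    flat_start = np.flatnonzero(start.ravel())
    if len(flat_start) == 0:
        return (np.empty(0, int),) * 3
    gid = np.cumsum(start.ravel()) * inval.ravel()
    lengths = np.bincount(gid)[1:]
    rows = flat_start // m
    col_start = flat_start % m
    col_end = col_start + lengths - 1
    return rows, col_start, col_end


def _batch_dilation_filter(
    vals: np.ndarray,
    valid: np.ndarray,
    t: np.ndarray,
    cfg: PrepConfig,
) -> None:
    """In-place dilation-speed filtering over a (trials x samples) matrix.

    Speeds are taken between consecutive valid samples per row (nearest
    valid neighbours); rows with < 3 valid samples are left untouched.
    """
    n, m = vals.shape
    idx = np.arange(m, dtype=np.int32)
    rows = np.arange(n)[:, None]
    for _ in range(cfg.mad_passes):
        active = valid.sum(axis=1) >= 3
        if not active.any():
            return
        v = valid & active[:, None]
        p = np.where(v, idx[None, :], np.int32(-1))
        prev = np.empty_like(p)
        prev[:, 0] = -1
        np.maximum.accumulate(p[:, :-1], axis=1, out=prev[:, 1:])
        q = np.where(v, idx[None, :], np.int32(m))
        nxt = np.empty_like(q)
        nxt[:, -1] = m
        np.minimum.accumulate(q[:, :0:-1], axis=1, out=nxt[:, -2::-1])
        has_b = prev >= 0
        has_f = nxt < m
        pj = np.maximum(prev, 0)
        nj = np.minimum(nxt, m - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            back = np.abs(vals - vals[rows, pj]) / np.where(
                has_b, t[None, :] - t[pj], 1.0
            )
            fwd = np.abs(vals[rows, nj] - vals) / np.where(
                has_f, t[nj] - t[None, :], 1.0
            )
        back = np.where(has_b, back, -np.inf)
        fwd = np.where(has_f, fwd, -np.inf)
        if cfg.speed_method == "both":
            d = np.maximum(back, fwd)
        elif cfg.speed_method == "forward":
            d = np.where(has_f, fwd, back)
        else:
            raise ValueError(f"unknown speed method {cfg.speed_method!r}")
        dmask = v & (has_b | has_f)
        d = np.where(dmask, d, np.nan)
        med = _row_median_masked(d, dmask)
        with np.errstate(invalid="ignore"):
            mad = _row_median_masked(np.abs(d - med[:, None]), dmask)
        mad = mad * cfg.mad_constant
        if cfg.threshold_form == "median_plus_k_mad":
            thr = med + cfg.mad_k * mad
        elif cfg.threshold_form == "k_mad":
            thr = cfg.mad_k * mad
        else:
            raise ValueError(f"unknown threshold form {cfg.threshold_form!r}")
        with np.errstate(invalid="ignore"):
            flag = v & (d > thr[:, None])
        if not flag.any():
            return
        valid &= ~flag


def preprocess_trials(
    series_list: list["PupilSeries"], config: PrepConfig | None = None
) -> list[TrialPupilFeatures]:
    """Preprocess many trials at once.

    Trials sharing a common sampling grid (same start and spacing, lengths
    may differ) are stacked and run through a vectorized implementation of
    the same chain as :func:`preprocess_trial`; heterogeneous inputs fall
    back to the per-trial path.
    """
    cfg = config or PrepConfig()
    if not series_list:
        return []
    dts = [s.dt_ms for s in series_list]
    t0s = [s.t[0] for s in series_list]
    homogeneous = (
        len(series_list) > 1
        and np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9)
        and np.allclose(t0s, t0s[0], rtol=0, atol=1e-9)
    )
    if not homogeneous:
        return [preprocess_trial(s, cfg) for s in series_list]

    n = len(series_list)
    lengths = np.array([len(s.t) for s in series_list])
    m = int(lengths.max())
    ref = series_list[int(np.argmax(lengths))]
    t = ref.t
    for s in series_list:
        if not np.allclose(s.t, t[: len(s.t)], rtol=1e-9, atol=1e-6):
            return [preprocess_trial(s, cfg) for s in series_list]

    L = np.full((n, m), np.nan)
    R = np.full((n, m), np.nan)
    VL = np.zeros((n, m), dtype=bool)
    VR = np.zeros((n, m), dtype=bool)
    for i, s in enumerate(series_list):
        k = lengths[i]
        L[i, :k] = s.left_mm
        R[i, :k] = s.right_mm
        VL[i, :k] = s.valid_l
        VR[i, :k] = s.valid_r

    # range filter
    lo, hi = cfg.range_mm
    with np.errstate(invalid="ignore"):
        VL &= np.isfinite(L) & (L >= lo) & (L <= hi)
        VR &= np.isfinite(R) & (R >= lo) & (R <= hi)

    _batch_dilation_filter(L, VL, t, cfg)
    _batch_dilation_filter(R, VR, t, cfg)

    dt = float(dts[0])
    in_len = np.arange(m)[None, :] < lengths[:, None]
    IL = np.zeros((n, m), dtype=bool)
    IR = np.zeros((n, m), dtype=bool)
    n_blinks = np.zeros(n, dtype=int)
    for vals, valid, imp in ((L, VL, IL), (R, VR, IR)):
        # blink labelling + padding (runs are rare; loop over runs only)
        seg = valid | ~in_len
        rows, c0, c1 = _run_table(seg)
        for r, a, b in zip(rows, c0, c1):
            dur = t[b] - t[a] + dt
            if not cfg.blink_range_ms[0] <= dur <= cfg.blink_range_ms[1]:
                continue
            n_blinks[r] += 1
            k = lengths[r]
            pad = (t[:k] >= t[a] - cfg.blink_pad_ms) & (t[:k] < t[a])
            pad |= (t[:k] > t[b]) & (t[:k] <= t[b] + cfg.blink_pad_ms)
            valid[r, :k] &= ~pad
        # interpolation: one interp call per affected row
        seg = valid | ~in_len
        rows, c0, c1 = _run_table(seg)
        if len(rows):
            dur = t[c1] - t[c0] + dt
            left_ok = c0 > 0
            right_ok = c1 + 1 < m
            anchor_l = valid[rows, np.clip(c0 - 1, 0, m - 1)] & left_ok
            anchor_r = (
                valid[rows, np.clip(c1 + 1, 0, m - 1)]
                & in_len[rows, np.clip(c1 + 1, 0, m - 1)]
                & right_ok
            )
            eligible = (dur <= cfg.max_gap_ms) & anchor_l & anchor_r
            for r in np.unique(rows[eligible]):
                sel = eligible & (rows == r)
                cols = np.concatenate(
                    [np.arange(a, b + 1) for a, b in zip(c0[sel], c1[sel])]
                )
                src = valid[r] & in_len[r]
                vals[r, cols] = np.interp(t[cols], t[src], vals[r, src])
                imp[r, cols] = True

    UL = VL | IL
    UR = VR | IR
    both = UL & UR
    usable = UL | UR
    lv = np.where(UL, L, np.nan)
    rv = np.where(UR, R, np.nan)
    value = np.where(both, 0.5 * (lv + rv), np.where(UL, lv, rv))

    base = (t >= cfg.baseline_window_ms[0]) & (t < cfg.baseline_window_ms[1])
    resp = (t >= cfg.sepr_window_ms[0]) & (t < cfg.sepr_window_ms[1])

    def _masked_mean(mask_cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sel = usable & in_len & mask_cols[None, :]
        cnt = sel.sum(axis=1)
        with np.errstate(invalid="ignore"):
            s = np.where(sel, value, 0.0).sum(axis=1)
            mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
        return mean, cnt

    bps, n_base = _masked_mean(base)
    resp_mean, n_resp = _masked_mean(resp)
    frac = (usable & in_len).sum(axis=1) / lengths
    included = frac >= cfg.min_valid_fraction

    out = []
    for i in range(n):
        if n_base[i] == 0:
            out.append(
                TrialPupilFeatures(
                    bps=float("nan"), sepr=float("nan"),
                    valid_fraction=float(frac[i]), included=False,
                    n_blinks=int(n_blinks[i]),
                )
            )
            continue
        sepr = float("nan")
        if included[i] and n_resp[i] > 0:
            sepr = float(resp_mean[i] - bps[i])
        out.append(
            TrialPupilFeatures(
                bps=float(bps[i]),
                sepr=sepr,
                valid_fraction=float(frac[i]),
                included=bool(included[i]),
                n_blinks=int(n_blinks[i]),
            )
        )
    return out
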