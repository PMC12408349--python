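"""Directed spectral interaction scores between simultaneous regions.

Spikes are binned at 12.5 ms over the whole recording (no task
alignment), averaged across the neurons of each region (regions with
fewer than ten neurons are excluded), cut into non-overlapping 10-s
segments, and the pair's cross-spectral density matrix is estimated by
multitaper averaging over segments and tapers.  Nonparametric spectral
Granger scores per direction are obtained by Wilson's spectral matrix
factorization (S = psi psi^H with causal psi), which yields the
transfer function H and innovation covariance Sigma without fitting an
autoregressive model; the per-frequency Granger measure

    f_{x->y}(w) = ln[ S_yy(w) / (S_yy(w) - |H_yx(w)|^2 (Sxx - Sxy^2/Syy)) ]

is averaged across the full positive-frequency band into a single score
per directed pair.  Significance uses a permutation that randomly swaps
the two region labels segment by segment; p-values across pairs are
Benjamini-Yekutieli corrected, and sessions combine by mean score plus
Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from . import aggregate
from .core_data import SessionBundle

BIN_S = 0.0125
SEGMENT_S = 10.0
MIN_NEURONS = 10
NW_DEFAULT = 3.0
K_TAPERS_DEFAULT = 5
M_PERMUTATIONS = 1000


# ---------------------------------------------------------------------------
# rate series
# ---------------------------------------------------------------------------

def region_rate_series(bundle: SessionBundle, bin_s: float = BIN_S,
                       min_neurons: int = MIN_NEURONS,
                       duration: float | None = None):
    """Across-neuron mean binned spike counts per region, whole recording.

    Returns (series dict region -> array, fs).  Regions with fewer than
    ``min_neurons`` well-isolated neurons are excluded.
    """
    if duration is None:
        duration = float(bundle.spikes["time_s"].max()) + bin_s
    edges = np.arange(0.0, duration + bin_s, bin_s)
    out = {}
    for region in bundle.regions:
        ids = bundle.neuron_ids(region=region)
        if ids.size < min_neurons:
            continue
        sel = bundle.spikes["neuron_id"].isin(ids)
        t = bundle.spikes.loc[sel, "time_s"].to_numpy(float)
        counts, _ = np.histogram(t, bins=edges)
        out[region] = counts / ids.size
    return out, 1.0 / bin_s


# ---------------------------------------------------------------------------
# multitaper cross-spectra
# ---------------------------------------------------------------------------

def segment_cross_spectra(x: np.ndarray, y: np.ndarray, fs: float,
                          segment_s: float = SEGMENT_S,
                          nw: float = NW_DEFAULT,
                          k_tapers: int = K_TAPERS_DEFAULT):
    """Per-segment multitaper cross-spectral matrices.

    Returns (S_seg, freqs) where S_seg is (n_segments, n_freq, 2, 2)
    complex, already averaged over tapers.  Needs >= 2 complete
    segments.
    """
    n_per = int(round(segment_s * fs))
    n_seg = min(x.size, y.size) // n_per
    if n_seg < 2:
        raise ValueError("need at least two complete segments")
    tapers = dpss(n_per, nw, Kmax=k_tapers)           # (K, n_per)
    norm = np.sum(tapers ** 2, axis=1)                # per-taper power
    data = np.stack([x[:n_seg * n_per].reshape(n_seg, n_per),
                     y[:n_seg * n_per].reshape(n_seg, n_per)])  # (2,S,n)
    data = data - data.mean(axis=2, keepdims=True)
    # (2, S, K, F)
    fft = np.fft.rfft(data[:, :, None, :] * tapers[None, None, :, :], axis=3)
    fft /= np.sqrt(norm[None, None, :, None] * fs)
    # cross spectra per segment, averaged over tapers
    s_seg = np.einsum("askf,bskf->sfab", fft, np.conj(fft)) / k_tapers
    freqs = np.fft.rfftfreq(n_per, d=1.0 / fs)
    return s_seg, freqs


# ---------------------------------------------------------------------------
# Wilson spectral matrix factorization
# ---------------------------------------------------------------------------

def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part of a spectral function given on the full FFT grid
    (axis 0 = frequency): zero the negative lags, halve lag zero (upper
    triangle kept for the lag-0 matrix)."""
    n = g.shape[0]
    # lag coefficients of the causal factor are real for real processes
    gam = np.real(np.fft.ifft(g, axis=0)).astype(complex)
    beta0 = 0.5 * gam[0]
    gam[0] = np.triu(beta0)
    gam[n // 2 + 1:] = 0.0
    return np.fft.fft(gam, axis=0)


def _inv22(m: np.ndarray) -> np.ndarray:
    """Batched explicit inverse of (n, 2, 2) matrices."""
    det = m[:, 0, 0] * m[:, 1, 1] - m[:, 0, 1] * m[:, 1, 0]
    out = np.empty_like(m)
    out[:, 0, 0] = m[:, 1, 1]
    out[:, 1, 1] = m[:, 0, 0]
    out[:, 0, 1] = -m[:, 0, 1]
    out[:, 1, 0] = -m[:, 1, 0]
    return out / det[:, None, None]


def wilson_factorize(S: np.ndarray, max_iter: int = 30,
                     tol: float = 1e-6):
    """Factorize a one-sided spectral density S(f) = H Sigma H^H.

    ``S`` is (n_freq, d, d) on the rfft grid (0..Nyquist inclusive).
    Returns (H, Sigma) with H on the same one-sided grid.
    """
    n_freq, d, _ = S.shape
    n = 2 * (n_freq - 1)
    # full grid with conjugate symmetry
    s_full = np.empty((n, d, d), dtype=complex)
    s_full[:n_freq] = S
    # S(-f) is the elementwise conjugate of S(f) for a real process
    s_full[n_freq:] = np.conj(S[-2:0:-1])
    # regularize: tiny diagonal ridge for numerical PD
    ridge = 1e-12 * np.mean(np.abs(np.diagonal(s_full, axis1=1, axis2=2)))
    s_full += (ridge + 1e-30) * np.eye(d)[None]

    gam = np.real(np.fft.ifft(s_full, axis=0))
    try:
        h0 = np.linalg.cholesky(gam[0]).T.conj()
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(gam[0])
        h0 = (v * np.sqrt(np.maximum(w, 1e-12))).T.conj()
    psi = np.tile(h0[None], (n, 1, 1)).astype(complex)
    eye = np.eye(d)
    inv = _inv22 if d == 2 else np.linalg.inv
    for _ in range(max_iter):
        inv_psi = inv(psi)
        g = inv_psi @ s_full @ np.conj(inv_psi).transpose(0, 2, 1) + eye
        gp = _plus_operator(g)
        psi_new = psi @ gp
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-30)
        psi = psi_new
        if delta < tol:
            break
    a0 = np.real(np.fft.ifft(psi, axis=0)[0])
    sigma = a0 @ a0.T
    h = psi[:n_freq] @ np.linalg.inv(a0)
    return h, sigma


def granger_from_spectra(S: np.ndarray):
    """Directed per-frequency Granger measures from a one-sided 2x2
    spectral matrix; returns (g_xy, g_yx) arrays (x->y and y->x)."""
    h, sigma = wilson_factorize(S)
    s_xx = np.real(S[:, 0, 0])
    s_yy = np.real(S[:, 1, 1])
    # conditional innovation variances
    sig_x_given_y = sigma[0, 0] - sigma[0, 1] ** 2 / max(sigma[1, 1], 1e-30)
    sig_y_given_x = sigma[1, 1] - sigma[0, 1] ** 2 / max(sigma[0, 0], 1e-30)
    denom_y = s_yy - np.abs(h[:, 1, 0]) ** 2 * sig_x_given_y
    denom_x = s_xx - np.abs(h[:, 0, 1]) ** 2 * sig_y_given_x
    with np.errstate(divide="ignore", invalid="ignore"):
        g_xy = np.log(s_yy / np.maximum(denom_y, 1e-30))
        g_yx = np.log(s_xx / np.maximum(denom_x, 1e-30))
    return np.maximum(np.nan_to_num(g_xy), 0.0), \
        np.maximum(np.nan_to_num(g_yx), 0.0)


@dataclass
class GrangerResult:
    source: str
    target: str
    score: float
    p: float = np.nan
    p_corrected: float = np.nan


def granger_score(x, y, fs, segment_s: float = SEGMENT_S,
                  nw: float = NW_DEFAULT,
                  k_tapers: int = K_TAPERS_DEFAULT):
    """Frequency-averaged Granger score for both directions of a pair."""
    s_seg, _ = segment_cross_spectra(np.asarray(x, float),
                                     np.asarray(y, float), fs,
                                     segment_s, nw, k_tapers)
    g_xy, g_yx = granger_from_spectra(s_seg.mean(axis=0))
    return float(g_xy.mean()), float(g_yx.mean())


def _swap_spectra(s_seg: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """Average spectra with the two channels swapped on flipped segments."""
    swapped = s_seg[:, :, ::-1, :][:, :, :, ::-1]
    mix = np.where(flips[:, None, None, None], swapped, s_seg)
    return mix.mean(axis=0)


def granger_permutation(x, y, fs, M: int = M_PERMUTATIONS, seed=None,
                        segment_s: float = SEGMENT_S,
                        nw: float = NW_DEFAULT,
                        k_tapers: int = K_TAPERS_DEFAULT):
    """Permutation p-values per direction by random segment label swaps.

    p = #{pseudo >= observed} / (M + 1), the raw counting form; a zero
    count gives p = 0, which downstream Fisher combination clips.
    """
    rng = np.random.default_rng(seed)
    s_seg, _ = segment_cross_spectra(np.asarray(x, float),
                                     np.asarray(y, float), fs,
                                     segment_s, nw, k_tapers)
    g_xy, g_yx = granger_from_spectra(s_seg.mean(axis=0))
    obs_xy, obs_yx = float(g_xy.mean()), float(g_yx.mean())
    n_seg = s_seg.shape[0]
    count_xy = count_yx = 0
    for _ in range(M):
        flips = rng.random(n_seg) < 0.5
        p_xy, p_yx = granger_from_spectra(_swap_spectra(s_seg, flips))
        if p_xy.mean() >= obs_xy:
            count_xy += 1
        if p_yx.mean() >= obs_yx:
            count_yx += 1
    return (obs_xy, count_xy / (M + 1.0)), (obs_yx, count_yx / (M + 1.0))


def session_granger(bundle: SessionBundle, M: int = M_PERMUTATIONS,
                    seed=None, bin_s: float = BIN_S,
                    min_neurons: int = MIN_NEURONS,
                    segment_s: float = SEGMENT_S,
                    q: float = 0.01) -> pd.DataFrame:
    """All directed region pairs of one session, BY-corrected.

    Output columns: session, source, target, score, p, significant.
    """
    series, fs = region_rate_series(bundle, bin_s=bin_s,
                                    min_neurons=min_neurons)
    regions = sorted(series)
    ss = np.random.SeedSequence(seed)
    rows = []
    pairs = [(a, b) for i, a in enumerate(regions)
             for b in regions[i + 1:]]
    for (a, b), child in zip(pairs, ss.spawn(max(1, len(pairs)))):
        (s_ab, p_ab), (s_ba, p_ba) = granger_permutation(
            series[a], series[b], fs, M=M,
            seed=child, segment_s=segment_s)
        rows.append({"session": bundle.session_id, "source": a,
                     "target": b, "score": s_ab, "p": p_ab})
        rows.append({"session": bundle.session_id, "source": b,
                     "target": a, "score": s_ba, "p": p_ba})
    df = pd.DataFrame(rows)
    if len(df):
        df["significant"] = aggregate.fdr(df["p"].to_numpy(), q=q,
                                          method="by")
    return df


def combine_sessions(tables: list[pd.DataFrame], q: float = 0.01) -> pd.DataFrame:
    """Combine directed-pair results across sessions: mean score plus
    Fisher's combined p, then BY correction across pairs."""
    cat = pd.concat(tables, ignore_index=True)
    rows = []
    for (a, b), grp in cat.groupby(["source", "target"]):
        rows.append({
            "source": a, "target": b,
            "score": float(grp["score"].mean()),
            "p": aggregate.fisher_combine(
                np.clip(grp["p"].to_numpy(float), aggregate.P_FLOOR, 1.0)),
            "n_sessions": len(grp),
        })
    df = pd.DataFrame(rows)
    df["significant"] = aggregate.fdr(df["p"].to_numpy(), q=q, method="by")
    return df
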