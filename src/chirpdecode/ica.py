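"""Extended-infomax independent component analysis.

The unmixing is learned by natural-gradient block updates with a
sign-switching (sub-/super-Gaussian) nonlinearity, on training data only;
the learned sphering+unmixing is then applied unchanged to held-out data.
Components are ordered by descending mean projected variance, and the
evoked-response components are selected automatically by correlating each
component's chirp-locked average with the canonical N100/P300 template
(replacing manual visual inspection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synth import Recording, canonical_erp

__all__ = [
    "IcaDecomposition",
    "fit_extended_infomax",
    "project_components",
    "select_erp_components",
]


@dataclass
class IcaDecomposition:
    sphering: np.ndarray       # channels x channels
    unmixing: np.ndarray       # components x channels (in sphered space)
    mixing: np.ndarray         # channels x components, pinv(unmixing @ sphering)
    component_order: np.ndarray  # permutation applied (descending variance)
    seed: int | None
    n_iterations: int
    converged: bool

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


def _as_array(data) -> np.ndarray:
    if isinstance(data, Recording):
        return data.data
    return np.asarray(data, dtype=float)


def fit_extended_infomax(
    data: np.ndarray | Recording,
    seed: int | None = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
    block: int = 256,
    l_rate: float | None = None,
    anneal_deg: float = 60.0,
    anneal_step: float = 0.98,
    ext_interval: int = 1,
    n_kurt_samples: int = 6000,
) -> IcaDecomposition:
    """Learn an ICA decomposition by the extended-infomax rule.

    Data are sphered to unit covariance, then the square unmixing matrix is
    updated in randomized blocks with
    ``W <- W + lr * (block*I - K*tanh(u)u' - uu') W`` where the diagonal sign
    matrix ``K`` tracks the kurtosis sign of each component.  The learning
    rate is annealed whenever the weight-update direction turns by more than
    ``anneal_deg`` degrees.  Non-convergence is reported via the
    ``converged`` flag, not an exception.
    """
    X = _as_array(data)
    n_ch, n = X.shape
    if n < 20 * n_ch:
        warnings.warn(
            f"only {n} samples for {n_ch} channels; ICA estimates may be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    cov = (X @ X.T) / n
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= evals.max() * 1e-12:
        raise ValueError("data are rank deficient; drop degenerate channels first")
    sphering = (evecs / np.sqrt(evals)) @ evecs.T
    Xw = sphering @ X

    W = np.eye(n_ch)
    if l_rate is None:
        l_rate = 0.001 / np.log(n_ch) if n_ch > 1 else 0.001
    signs = np.ones(n_ch)  # +1 super-Gaussian, -1 sub-Gaussian
    BI = block * np.eye(n_ch)
    max_weight = 1e8

    old_delta = None
    n_iterations = 0
    converged = False
    for it in range(max_iter):
        perm = rng.permutation(n)
        W_old = W.copy()
        blew_up = False
        for b0 in range(0, n - block + 1, block):
            u = W @ Xw[:, perm[b0:b0 + block]]
            y = np.tanh(u)
            W = W + l_rate * ((BI - (signs[:, None] * y) @ u.T - u @ u.T) @ W)
            if not np.isfinite(W).all() or np.abs(W).max() > max_weight:
                blew_up = True
                break
        if blew_up:
            W = np.eye(n_ch)
            old_delta = None
            l_rate *= 0.5
            if l_rate < 1e-10:
                break
            continue

        if (it + 1) % ext_interval == 0:
            take = rng.permutation(n)[: min(n_kurt_samples, n)]
            u = W @ Xw[:, take]
            m2 = np.mean(u**2, axis=1)
            m4 = np.mean(u**4, axis=1)
            kurt = m4 / m2**2 - 3.0
            signs = np.where(kurt >= 0, 1.0, -1.0)

        delta = (W - W_old).ravel()
        wchange = float(np.sqrt(delta @ delta))
        if old_delta is not None:
            denom = np.sqrt((delta @ delta) * (old_delta @ old_delta))
            if denom > 0:
                angle = np.degrees(np.arccos(np.clip(delta @ old_delta / denom, -1, 1)))
                if angle > anneal_deg:
                    l_rate *= anneal_step
        old_delta = delta
        n_iterations = it + 1
        if wchange < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"extended infomax did not converge in {n_iterations} iterations",
            stacklevel=2,
        )

    unmixing = W
    mixing = np.linalg.pinv(unmixing @ sphering)
    act = unmixing @ Xw
    # mean projected variance: average channel-space variance explained by
    # each component when back-projected alone
    mpv = np.mean(mixing**2, axis=0) * act.var(axis=1)
    order = np.argsort(mpv)[::-1]
    unmixing = unmixing[order]
    mixing = mixing[:, order]
    return IcaDecomposition(
        sphering=sphering, unmixing=unmixing, mixing=mixing,
        component_order=order, seed=seed, n_iterations=n_iterations,
        converged=converged,
    )


def project_components(decomp: IcaDecomposition,
                       data: np.ndarray | Recording) -> np.ndarray:
    """Component activations ``unmixing @ sphering @ data`` (linear)."""
    X = _as_array(data)
    if X.shape[0] != decomp.sphering.shape[1]:
        raise ValueError(
            f"data has {X.shape[0]} channels, decomposition expects "
            f"{decomp.sphering.shape[1]}"
        )
    return decomp.unmixing @ (decomp.sphering @ X)


def select_erp_components(
    decomp: IcaDecomposition,
    activations: np.ndarray,
    chirp_onsets: np.ndarray,
    fs: float,
    k: int = 2,
    min_abs_r: float = 0.4,
    epoch_s: float = 0.5,
    filter_spec=None,
    return_scores: bool = False,
):
    """Rank components by |Pearson r| between their chirp-locked average and
    the canonical ERP template; return the top ``k`` at or above ``min_abs_r``.

    When the activations come from band-pass-filtered data, pass the
    ``filter_spec`` so the template is shaped by the same filter (the
    high-pass edge visibly distorts the slow positive wave; comparing
    against the raw template caps the attainable correlation).

    Scores are absolute-valued: ICA sign indeterminacy never affects the
    selection.  An empty selection (no component resembles the template) is
    returned with a warning so callers can fall back to all components.
    """
    activations = np.asarray(activations, dtype=float)
    if activations.shape[0] != decomp.n_components:
        raise ValueError("activations do not match the decomposition")
    L = int(round(epoch_s * fs))
    onsets = np.asarray(chirp_onsets, dtype=int)
    onsets = onsets[(onsets >= 0) & (onsets + L <= activations.shape[1])]
    if len(onsets) == 0:
        raise ValueError("no chirp event with a full epoch inside the data")

    template = canonical_erp(fs=fs, epoch_s=epoch_s)
    if filter_spec is not None:
        from .preprocess import filter_array
        pad = np.zeros(4 * len(filter_spec.coefficients) + len(template))
        pad[:len(template)] = template
        template = filter_array(filter_spec, pad)[:len(template)]
    template = template - template.mean()
    tnorm = np.sqrt(template @ template)

    scores = np.zeros(decomp.n_components)
    for c in range(decomp.n_components):
        ep = activations[c][onsets[:, None] + np.arange(L)]
        mean_wave = ep.mean(axis=0)
        mean_wave = mean_wave - mean_wave.mean()
        denom = np.sqrt(mean_wave @ mean_wave) * tnorm
        scores[c] = np.abs(mean_wave @ template) / denom if denom > 0 else 0.0

    ranked = np.argsort(scores)[::-1]
    selected = [int(c) for c in ranked[:k] if scores[c] >= min_abs_r]
    if not selected:
        warnings.warn(
            f"no component correlates with the ERP template at |r| >= "
            f"{min_abs_r}; selection is empty", stacklevel=2,
        )
    if return_scores:
        return selected, scores
    return selected
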