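"""End-to-end single-trial classification pipeline.

Protocol: band-pass filter; chronological 75/25 split per label; fit all
cleaning statistics (bad channels, ASR, ICA weights, component selection) on
the training span only; apply them unchanged to the held-out span; epoch
0-500 ms post-onset features; select the classifier by randomized inner
cross-validation; evaluate repeatedly on the fixed test set; calibrate
against label-shuffled nulls.  Four preprocessing variants are compared:
``pre_ica`` (cleaned channels), ``ica`` (selected component activations),
and each with an additional Kalman ERP-estimation stage
(``pre_ica_kalman``, ``ica_kalman``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__
from .synth import Recording, EventList, CHIRP
from .preprocess import (
    BadChannelCriteria, design_fir_bandpass, apply_filter,
    detect_bad_channels, select_calibration_mask, asr_fit, asr_process,
)
from .ica import fit_extended_infomax, project_components, select_erp_components
from .kalman import build_erp_model, kalman_filter_erp, epoch_signal
from .classify import (
    evaluate_repeated, permutation_test, compare_conditions,
)

VARIANTS = ("pre_ica", "ica", "pre_ica_kalman", "ica_kalman")

__all__ = [
    "PipelineConfig",
    "ConditionModel",
    "ConditionReport",
    "chronological_split",
    "fit_condition",
    "run_condition",
    "nested_comparison",
]


@dataclass
class PipelineConfig:
    """Knobs of the full analysis; defaults mirror the study protocol."""

    train_fraction: float = 0.75
    variants: tuple[str, ...] = VARIANTS
    n_repeats: int = 100
    n_perm: int = 100
    n_nested: int = 10
    alpha: float = 0.05
    seed: int = 0
    # preprocessing
    filter_low_hz: float = 2.0
    filter_high_hz: float = 30.0
    filter_order: int = 496
    criteria: BadChannelCriteria = field(default_factory=BadChannelCriteria)
    asr_cutoff: float = 5.0
    asr_min_clean_s: float = 30.0
    # ica
    ica_max_iter: int = 512
    n_erp_components: int = 2
    min_abs_r: float = 0.4
    # kalman / features
    kalman_ratio: float = 0.001
    epoch_s: float = 0.5
    # classifier
    n_folds: int = 10
    sigma_grid: tuple[float, ...] | None = None
    lambda_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not self.variants:
            raise ValueError("at least one variant must be requested")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}; choose from {VARIANTS}")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"] = dataclasses.asdict(self.criteria)
        return d


def chronological_split(events: EventList,
                        train_fraction: float = 0.75) -> tuple[EventList, EventList]:
    """Per label, the earliest ceil(fraction*n) events train; the rest test."""
    if len(events) == 0:
        raise ValueError("no events to split")
    train, test = [], []
    labels = sorted(set(e.label for e in events))
    for lab in labels:
        evs = [e for e in events if e.label == lab]
        if len(evs) < 2:
            raise ValueError(f"label {lab!r} has {len(evs)} events; need >= 2")
        n_train = int(np.ceil(train_fraction * len(evs)))
        n_train = min(n_train, len(evs) - 1) if n_train == len(evs) else n_train
        train.extend(evs[:n_train])
        test.extend(evs[n_train:])
    key = lambda e: (e.onset_sample, e.label)
    return (
        EventList(tuple(sorted(train, key=key)), events.fs),
        EventList(tuple(sorted(test, key=key)), events.fs),
    )


@dataclass
class ConditionModel:
    """Everything fitted on the training span, for transfer to test data."""

    filter_spec: object
    bad_channels: list
    bad_channel_reasons: dict
    asr_model: object
    ica: object | None
    selected_components: list | None
    component_scores: np.ndarray | None
    boundary_sample: int
    train_events: EventList
    test_events: EventList


def _seed_for(config: PipelineConfig, name: str) -> np.random.SeedSequence:
    streams = {"ica": 1, "folds": 2, "permutation": 3, "nested": 4}
    return np.random.SeedSequence([config.seed, streams[name]])


def fit_condition(recording: Recording, config: PipelineConfig,
                  need_ica: bool | None = None) -> ConditionModel:
    """Fit filter/bad-channel/ASR/ICA parameters from the training span only.

    The training span is every sample before the first test-event onset, so
    removing the test span from the input leaves the fit bit-identical.
    """
    spec = design_fir_bandpass(config.filter_low_hz, config.filter_high_hz,
                               config.filter_order, recording.fs)
    train_ev, test_ev = chronological_split(recording.events,
                                            config.train_fraction)
    boundary = int(test_ev.onsets().min())

    train_raw = Recording(
        data=recording.data[:, :boundary].copy(), fs=recording.fs,
        channel_labels=recording.channel_labels, events=train_ev)
    train_filt = apply_filter(spec, train_raw)
    bad, reasons = detect_bad_channels(train_filt, config.criteria,
                                       return_reasons=True)
    kept = train_filt.drop(bad)
    if kept.n_channels == 0:
        raise ValueError("all channels were rejected")

    mask = select_calibration_mask(kept, min_clean_s=config.asr_min_clean_s)
    asr = asr_fit(kept.data[:, mask], fs=recording.fs, cutoff=config.asr_cutoff)

    if need_ica is None:
        need_ica = any("ica" == v or v == "ica_kalman" for v in config.variants)
    decomp = None
    selected = None
    scores = None
    if need_ica:
        cleaned_train = asr_process(asr, kept.data)
        ica_seed = int(_seed_for(config, "ica").generate_state(1)[0] % (2**31))
        decomp = fit_extended_infomax(cleaned_train, seed=ica_seed,
                                      max_iter=config.ica_max_iter)
        act = project_components(decomp, cleaned_train)
        selected, scores = select_erp_components(
            decomp, act, train_ev.onsets(CHIRP), recording.fs,
            k=config.n_erp_components, min_abs_r=config.min_abs_r,
            epoch_s=config.epoch_s, filter_spec=spec, return_scores=True)
        if not selected:  # fall back to all components
            selected = list(range(decomp.n_components))

    return ConditionModel(
        filter_spec=spec, bad_channels=bad, bad_channel_reasons=reasons,
        asr_model=asr, ica=decomp, selected_components=selected,
        component_scores=scores, boundary_sample=boundary,
        train_events=train_ev, test_events=test_ev)


@dataclass
class VariantResult:
    metrics: dict | None
    permutation_p: float | None
    selected_hyperparams: list | None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "permutation_p": self.permutation_p,
            "selected_hyperparams": self.selected_hyperparams,
            "error": self.error,
        }


@dataclass
class ConditionReport:
    variants: dict
    removed_channels: list
    removed_reasons: dict
    selected_components: list | None
    component_scores: list | None
    config: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "removed_channels": list(self.removed_channels),
            "removed_reasons": self.removed_reasons,
            "selected_components": self.selected_components,
            "component_scores": self.component_scores,
            "variants": {k: v.to_dict() for k, v in self.variants.items()},
            "config": self.config,
        }


def _variant_signals(cleaned: Recording, model: ConditionModel,
                     variant: str, config: PipelineConfig) -> np.ndarray:
    if variant.startswith("pre_ica"):
        signals = cleaned.data
    else:
        if model.ica is None:
            raise ValueError("ICA was not fitted but an ICA variant was requested")
        act = project_components(model.ica, cleaned.data)
        signals = act[model.selected_components]
    if variant.endswith("kalman"):
        erp_model = build_erp_model(cleaned.fs, ratio=config.kalman_ratio)
        est = kalman_filter_erp(erp_model, signals,
                                cleaned.events.onsets())
        signals = np.atleast_2d(est.estimate)
    return signals


def _features(signals: np.ndarray, events: EventList, fs: float,
              epoch_s: float) -> tuple[np.ndarray, np.ndarray]:
    epochs, labels = epoch_signal(signals, events, fs=fs, window_s=epoch_s)
    X = epochs.reshape(len(epochs), -1)
    return X, labels


def run_condition(recording: Recording, config: PipelineConfig) -> ConditionReport:
    """Execute the full protocol for every requested variant.

    A failure inside one variant is captured in its report entry; the
    remaining variants still run.
    """
    model = fit_condition(recording, config)
    full_filt = apply_filter(model.filter_spec, recording).drop(model.bad_channels)
    cleaned = asr_process(model.asr_model, full_filt)

    fold_seed = _seed_for(config, "folds")
    perm_seed = _seed_for(config, "permutation")
    results: dict[str, VariantResult] = {}
    for variant in config.variants:
        try:
            signals = _variant_signals(cleaned, model, variant, config)
            Xtr, ytr = _features(signals, model.train_events, recording.fs,
                                 config.epoch_s)
            Xte, yte = _features(signals, model.test_events, recording.fs,
                                 config.epoch_s)
            rep = evaluate_repeated(
                Xtr, ytr, Xte, yte, n_repeats=config.n_repeats,
                seed=np.random.SeedSequence(
                    [int(fold_seed.generate_state(1)[0] % 2**31),
                     VARIANTS.index(variant)]),
                n_folds=config.n_folds, sigma_grid=config.sigma_grid,
                lambda_grid=config.lambda_grid)
            p = None
            if config.n_perm > 0:
                perm = permutation_test(
                    Xtr, ytr, Xte, yte, n_perm=config.n_perm,
                    seed=np.random.SeedSequence(
                        [int(perm_seed.generate_state(1)[0] % 2**31),
                         VARIANTS.index(variant)]),
                    observed_accuracy=rep.mean("accuracy"),
                    n_folds=config.n_folds, sigma_grid=config.sigma_grid,
                    lambda_grid=config.lambda_grid)
                p = perm.p_value
            results[variant] = VariantResult(
                metrics=rep.summary(), permutation_p=p,
                selected_hyperparams=rep.selected)
        except Exception as err:  # keep the other variants running
            results[variant] = VariantResult(
                metrics=None, permutation_p=None, selected_hyperparams=None,
                error=f"{variant}: {type(err).__name__}: {err}")

    return ConditionReport(
        variants=results,
        removed_channels=model.bad_channels,
        removed_reasons=model.bad_channel_reasons,
        selected_components=model.selected_components,
        component_scores=(None if model.component_scores is None
                          else [float(s) for s in model.component_scores]),
        config=config.echo(),
    )


def nested_comparison(recording: Recording, config: PipelineConfig) -> dict:
    """Model-stability comparison: independent re-runs, paired Wilcoxon.

    Each of ``n_nested`` re-runs uses fresh seeds for every random stage;
    for every pair of requested variants the paired per-run mean accuracy,
    FPR and FNR are compared with the two-sided Wilcoxon signed-rank test.
    """
    if config.n_nested < 2:
        raise ValueError("n_nested must be >= 2")
    base = _seed_for(config, "nested")
    per_variant: dict[str, dict[str, list[float]]] = {
        v: {"accuracy": [], "false_positive_rate": [], "false_negative_rate": []}
        for v in config.variants
    }
    for i, child in enumerate(base.spawn(config.n_nested)):
        sub = replace(config, seed=int(child.generate_state(1)[0] % 2**31),
                      n_perm=0)
        report = run_condition(recording, sub)
        for v in config.variants:
            res = report.variants[v]
            if res.error:
                raise RuntimeError(f"nested run {i} failed: {res.error}")
            for m in per_variant[v]:
                per_variant[v][m].append(res.metrics[m]["mean"])

    comparisons: dict = {}
    vs = list(config.variants)
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            key = f"{vs[i]}_vs_{vs[j]}"
            comparisons[key] = {}
            for m in ("accuracy", "false_positive_rate", "false_negative_rate"):
                res = compare_conditions(per_variant[vs[i]][m],
                                         per_variant[vs[j]][m])
                comparisons[key][m] = {
                    "p_value": res.p_value, "statistic": res.statistic,
                    "n_used": res.n_used, "n_zero": res.n_zero,
                }
    return {"per_variant": per_variant, "comparisons": comparisons,
            "n_nested": config.n_nested}
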