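"""End-to-end augmented-vs-real evaluation orchestration.

Protocol: session 1 of the real recordings is the template (training) set,
sessions 2+ are the test set. The GAN converter is trained on the template
windows, simulated trials are converted, and classifiers are trained either
on real template windows alone or on template windows mixed 1:1 with
converted windows. CSP filters are always fitted on the respective training
set only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mebci import pipeline as pl
from mebci.gan import TrainConfig, convert, train_gan
from mebci.synthetic import split_sessions

__all__ = ["ComparisonResult", "augmentation_comparison", "evaluate_condition"]


@dataclass
class ComparisonResult:
    report_real: pl.ClassificationReport
    report_aug: pl.ClassificationReport
    comparison: dict
    loss_history: dict

    def to_json(self) -> dict:
        def rep(r: pl.ClassificationReport) -> dict:
            return {
                "condition": r.condition,
                "validation_accuracy": r.validation_accuracy,
                "test_accuracy": r.test_accuracy,
                "confusion": {k: v.tolist() for k, v in r.confusion.items()},
                "notes": r.notes,
            }

        return {
            "real_only": rep(self.report_real),
            "augmented": rep(self.report_aug),
            "comparison": self.comparison,
        }

    def write_tables(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep in (self.report_real, self.report_aug):
            rows = ["classifier,validation_accuracy,test_accuracy"]
            for name in sorted(rep.test_accuracy):
                rows.append(
                    f"{name},{rep.validation_accuracy[name]:.2f},"
                    f"{rep.test_accuracy[name]:.2f}"
                )
            (out_dir / f"accuracy_{rep.condition}.csv").write_text(
                "\n".join(rows) + "\n"
            )
            for name, cm in rep.confusion.items():
                header = "," + ",".join(rep.classes)
                lines = [header] + [
                    f"{cls}," + ",".join(str(int(x)) for x in row)
                    for cls, row in zip(rep.classes, cm)
                ]
                (out_dir / f"confusion_{rep.condition}_{name}.csv").write_text(
                    "\n".join(lines) + "\n"
                )


def evaluate_condition(
    train_wb: pl.WindowBatch,
    test_wb: pl.WindowBatch,
    condition: str,
    m_pairs: int = 3,
    n_folds: int = 5,
    seed: int = 0,
    classifiers: dict | None = None,
) -> pl.ClassificationReport:
    """Fit CSP + classifiers on the training windows, report on the test set."""
    classifiers = classifiers or pl.default_classifiers(seed)
    bank = pl.csp_fit(train_wb, m=m_pairs)
    x_train = pl.csp_features(train_wb, bank)
    x_test = pl.csp_features(test_wb, bank)
    val = pl.train_and_validate(x_train, train_wb.y, classifiers, n_folds, seed)
    models = pl.fit_models(x_train, train_wb.y, classifiers)
    return pl.evaluate_test(models, x_test, test_wb.y, val, condition)


def _subsample(wb: pl.WindowBatch, n: int, rng: np.random.Generator) -> pl.WindowBatch:
    if n >= len(wb.labels):
        return wb
    # class-balanced draw
    y = wb.y
    idx = []
    per = max(1, n // len(set(y.tolist())))
    for c in np.unique(y):
        pool = np.where(y == c)[0]
        take = min(per, len(pool))
        idx.extend(rng.choice(pool, size=take, replace=False))
    idx = np.array(sorted(idx))
    return pl.WindowBatch(
        wb.windows[idx], tuple(wb.labels[i] for i in idx), wb.fs, wb.source,
        wb.classes,
    )


def augmentation_comparison(
    real: pl.TrialSet,
    sim: pl.TrialSet,
    cfg: dict,
    classifiers: dict | None = None,
) -> ComparisonResult:
    """Full comparison; ``cfg`` follows the layout of mebci.config defaults."""
    g, p = cfg["gan"], cfg["pipeline"]
    seed = cfg["seed"]
    window_len = p["window_len"]

    template, test = split_sessions(real)
    template = pl.preprocess(template, tuple(p["band"]), p["filter_order"])
    test = pl.preprocess(test, tuple(p["band"]), p["filter_order"])
    sim_pp = pl.preprocess(sim, tuple(p["band"]), p["filter_order"])

    tc = TrainConfig(
        iterations=g["iterations"], d_learning_rate=g["d_learning_rate"],
        g_learning_rate=g["g_learning_rate"], clip_value=g["clip_value"],
        decay=g["decay"], batch_size=g["batch_size"], gen_batch=g["gen_batch"],
        window_len=g["window_len"], seed=seed,
        d_interval=g.get("d_interval", 1), g_interval=g.get("g_interval", 1),
        sim_negatives=g.get("sim_negatives", 0.5),
    )
    trained = train_gan(sim_pp, template, tc)
    # converted "practical" EEG goes through the same preprocessing as the
    # real recordings before windowing
    converted = pl.preprocess(convert(trained, sim_pp), tuple(p["band"]),
                              p["filter_order"])

    wb_template = pl.slice_windows(template, window_len, source="real")
    wb_test = pl.slice_windows(test, window_len, source="real")
    wb_fake = pl.slice_windows(converted, window_len, source="fake")
    rng = np.random.default_rng(seed + 17)
    n_fake = int(round(p.get("mix_ratio", 1.0) * len(wb_template.labels)))
    wb_fake = _subsample(wb_fake, n_fake, rng)
    wb_mixed = wb_template.concat(wb_fake)

    rep_real = evaluate_condition(
        wb_template, wb_test, "real_only", p["csp_pairs"], p["n_folds"], seed,
        classifiers,
    )
    rep_aug = evaluate_condition(
        wb_mixed, wb_test, "augmented", p["csp_pairs"], p["n_folds"], seed,
        classifiers,
    )
    comparison = pl.compare_conditions(rep_aug, rep_real)
    return ComparisonResult(rep_real, rep_aug, comparison, trained.loss_history)
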