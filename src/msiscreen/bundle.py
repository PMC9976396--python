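"""Model bundle persistence.

A bundle is a directory with a human-readable ``manifest.json`` (format
version, config snapshot, seed, split ids, per-locus AUC/selection
table), a ``loci.tsv`` mirror of the per-locus table, and a
``models.joblib`` binary store holding the fitted estimators and the
stable baseline profiles used for plotting. Manifests contain no
timestamps, so identical training runs serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np

from . import __version__
from .regions import MsLocus, config_from_dict, config_to_dict
from .training import FittedModel, LocusModelPair, ModelBundle

FORMAT_VERSION = "1"

__all__ = ["FORMAT_VERSION", "BundleError", "save_bundle", "load_bundle"]


class BundleError(RuntimeError):
    """Bundle missing, corrupt, or written by an incompatible version."""


def _pair_meta(pair: LocusModelPair) -> dict:
    return {
        "coverage_pass": pair.coverage_pass,
        "retained": pair.retained,
        "auc_logreg": None if np.isnan(pair.auc_logreg) else round(pair.auc_logreg, 6),
        "auc_svc": None if np.isnan(pair.auc_svc) else round(pair.auc_svc, 6),
        "n_train_stable": pair.n_train_stable,
        "n_train_unstable": pair.n_train_unstable,
        "params_logreg": pair.model_logreg.params if pair.model_logreg else None,
        "params_svc": pair.model_svc.params if pair.model_svc else None,
    }


def save_bundle(bundle: ModelBundle, path: str | Path) -> Path:
    """Serialize a bundle to a directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "tool_version": __version__,
        "seed": bundle.seed,
        "config": config_to_dict(bundle.config),
        "split": bundle.split,
        "panel": [
            {"name": l.name, "chrom": l.chrom, "start": l.start,
             "end": l.end, "source": l.source}
            for l in bundle.panel
        ],
        "loci": {name: _pair_meta(pair) for name, pair in sorted(bundle.pairs.items())},
    }
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    with open(path / "loci.tsv", "w") as fh:
        fh.write("locus\tcoverage_pass\tauc_logreg\tauc_svc\tretained\n")
        for name, pair in sorted(bundle.pairs.items()):
            auc_lr = "NA" if np.isnan(pair.auc_logreg) else f"{pair.auc_logreg:.4f}"
            auc_svc = "NA" if np.isnan(pair.auc_svc) else f"{pair.auc_svc:.4f}"
            fh.write(
                f"{name}\t{int(pair.coverage_pass)}\t{auc_lr}\t{auc_svc}\t"
                f"{int(pair.retained)}\n"
            )
    store = {
        "models": {
            name: (
                pair.model_logreg.estimator if pair.model_logreg else None,
                pair.model_svc.estimator if pair.model_svc else None,
            )
            for name, pair in bundle.pairs.items()
        },
        "baselines": bundle.baselines,
    }
    joblib.dump(store, path / "models.joblib")
    return path


def load_bundle(path: str | Path) -> ModelBundle:
    """Load a bundle directory; hard error on format-version mismatch."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"{path}: no manifest.json - not a model bundle")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise BundleError(
            f"{path}: bundle format version {version!r} != supported {FORMAT_VERSION!r}"
        )
    store = joblib.load(path / "models.joblib")
    panel = [
        MsLocus(name=rec["name"], chrom=rec["chrom"], start=rec["start"],
                end=rec["end"], source=rec.get("source"))
        for rec in manifest["panel"]
    ]
    pairs: dict[str, LocusModelPair] = {}
    for name, meta in manifest["loci"].items():
        est_lr, est_svc = store["models"][name]
        pairs[name] = LocusModelPair(
            locus_name=name,
            model_logreg=FittedModel("logreg", est_lr, meta["params_logreg"] or {})
            if est_lr is not None else None,
            model_svc=FittedModel("svc", est_svc, meta["params_svc"] or {})
            if est_svc is not None else None,
            auc_logreg=float("nan") if meta["auc_logreg"] is None else meta["auc_logreg"],
            auc_svc=float("nan") if meta["auc_svc"] is None else meta["auc_svc"],
            coverage_pass=meta["coverage_pass"],
            retained=meta["retained"],
            n_train_stable=meta["n_train_stable"],
            n_train_unstable=meta["n_train_unstable"],
        )
    return ModelBundle(
        panel=panel,
        config=config_from_dict(manifest["config"]),
        pairs=pairs,
        split=manifest["split"],
        baselines=store.get("baselines", {}),
        version=version,
        seed=manifest["seed"],
    )
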