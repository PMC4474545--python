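"""Self-contained JSON persistence for trained detectors.

A model file carries everything prediction needs — feature names, linear
weights and bias, the chosen C, per-feature scaling ranges, word-type
vocabularies, length statistics, the corpus count table and the lexicons —
so no binary artifacts or external resources are required at load time.
A sentence model embeds the abbreviation model it depends on and records
its hash.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .features import AbbreviationFeaturizer, SentenceFeaturizer
from .lexicon import Lexicon
from .model import (
    AbbreviationDetector,
    LinearPeriodSVM,
    RangeUnitScaler,
    SentenceBoundaryDetector,
)
from .stats import CountTable, LengthStats, scaling_combos

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model"]


def _hash(d: dict) -> str:
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, ensure_ascii=False).encode("utf-8")
    ).hexdigest()[:16]


def _svm_to_dict(svm: LinearPeriodSVM) -> dict:
    return {
        "C": svm.C_,
        "coef": svm.coef_.tolist(),
        "intercept": svm.intercept_,
        "classes": np.asarray(svm.classes_).astype(int).tolist(),
        "scaler": {"min": svm.scaler_.min_.tolist(), "max": svm.scaler_.max_.tolist()},
    }


def _svm_from_dict(d: dict) -> LinearPeriodSVM:
    svm = LinearPeriodSVM(C=d["C"])
    scaler = RangeUnitScaler()
    scaler.min_ = np.asarray(d["scaler"]["min"], dtype=float)
    scaler.max_ = np.asarray(d["scaler"]["max"], dtype=float)
    rng = scaler.max_ - scaler.min_
    scaler.scale_ = np.where(rng > 0, 2.0 / np.where(rng > 0, rng, 1.0), 0.0)
    svm.scaler_ = scaler
    svm.C_ = d["C"]
    svm.coef_ = np.asarray(d["coef"], dtype=float)
    svm.intercept_ = float(d["intercept"])
    svm.classes_ = np.asarray(d["classes"], dtype=int)
    return svm


def model_to_dict(model) -> dict:
    if isinstance(model, SentenceBoundaryDetector):
        kind = "sentence"
    elif isinstance(model, AbbreviationDetector):
        kind = "abbreviation"
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    fz = model.featurizer_
    d = {
        "kind": kind,
        "feature_sets": list(fz.sets_),
        "alpha": model.alpha,
        "feature_names": list(model.feature_names_),
        "svm": _svm_to_dict(model.svm_),
        "length_stats": fz.length_stats_.to_dict() if fz.length_stats_ else None,
        "count_table": model.count_table.to_rows() if model.count_table else [],
        "mddict": sorted(model.mddict.entries) if model.mddict else [],
    }
    if kind == "abbreviation":
        d["vocab"] = list(fz.vocab_)
    else:
        d["l_vocab"] = list(fz.l_vocab_)
        d["r_vocab"] = list(fz.r_vocab_)
        d["ccdict"] = sorted(model.ccdict.entries) if model.ccdict else []
        d["ccdict_plain_membership"] = model.ccdict_plain_membership
        if model.abbrev_model is not None:
            ab = model_to_dict(model.abbrev_model)
            d["abbrev_model"] = ab
            d["abbrev_model_hash"] = ab["config_hash"]
    d["config_hash"] = _hash(d)
    return d


def _restore_common(d: dict):
    table = CountTable.from_rows(d.get("count_table", []))
    mddict = Lexicon(d.get("mddict", []), role="MDDict")
    stats = (
        LengthStats(**d["length_stats"]) if d.get("length_stats") is not None else None
    )
    return table, mddict, stats


def model_from_dict(d: dict):
    table, mddict, stats = _restore_common(d)
    if d["kind"] == "abbreviation":
        det = AbbreviationDetector(
            feature_sets=tuple(d["feature_sets"]),
            mddict=mddict,
            count_table=table,
            alpha=d["alpha"],
            C=d["svm"]["C"],
        )
        fz = AbbreviationFeaturizer(
            feature_sets=det.feature_sets,
            mddict=mddict,
            count_table=table,
            alpha=d["alpha"],
        )
        fz.sets_ = tuple(d["feature_sets"])
        fz.length_stats_ = stats
        fz.vocab_ = list(d.get("vocab", []))
        fz._vocab_index = {t: i for i, t in enumerate(fz.vocab_)}
        fz._combos = scaling_combos()
        fz.feature_names_ = list(d["feature_names"])
    elif d["kind"] == "sentence":
        ccdict = Lexicon(d.get("ccdict", []), role="CCDict")
        abbrev_model = (
            model_from_dict(d["abbrev_model"]) if d.get("abbrev_model") else None
        )
        det = SentenceBoundaryDetector(
            feature_sets=tuple(d["feature_sets"]),
            mddict=mddict,
            ccdict=ccdict,
            count_table=table,
            abbrev_model=abbrev_model,
            alpha=d["alpha"],
            ccdict_plain_membership=d.get("ccdict_plain_membership", False),
            C=d["svm"]["C"],
        )
        fz = SentenceFeaturizer(
            feature_sets=det.feature_sets,
            mddict=mddict,
            ccdict=ccdict,
            count_table=table,
            abbrev_model=abbrev_model,
            alpha=d["alpha"],
            ccdict_plain_membership=det.ccdict_plain_membership,
        )
        fz.sets_ = tuple(d["feature_sets"])
        fz.length_stats_ = stats
        fz.l_vocab_ = list(d.get("l_vocab", []))
        fz.r_vocab_ = list(d.get("r_vocab", []))
        fz._l_index = {t: i for i, t in enumerate(fz.l_vocab_)}
        fz._r_index = {t: i for i, t in enumerate(fz.r_vocab_)}
        fz.feature_names_ = list(d["feature_names"])
    else:
        raise ValueError(f"unknown model kind {d.get('kind')!r}")
    det.featurizer_ = fz
    det.feature_names_ = list(d["feature_names"])
    det.svm_ = _svm_from_dict(d["svm"])
    det.C_ = det.svm_.C_
    det.classes_ = det.svm_.classes_
    return det


def save_model(model, path) -> dict:
    d = model_to_dict(model)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, ensure_ascii=False, indent=1)
    return d


def load_model(path):
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
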