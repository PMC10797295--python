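"""Subset-model experiment harness.

Trains a parent model on the full training split plus one model per
subset specification (CT-only, PET-only, single-timepoint, healthy-only /
tumor-only, organ-subtracted), evaluates every model on the same test
cases, and tests whether the parent's per-case DSC exceeds each subset
model's (one-sided, Bonferroni-corrected across the comparisons made).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import compare_models, evaluate_cases
from .inference import predict_case
from .training import (PreparedCase, SubsetSpec, TrainConfig, TrainedModel,
                       train_on_cases)
from .unet import NetConfig


def _subset_name(s: SubsetSpec) -> str:
    parts = []
    if s.modality != "both":
        parts.append(s.modality)
    if s.timepoints is not None:
        parts.append("t" + "+".join(f"{t:g}h" for t in s.timepoints))
    if s.tumor != "all":
        parts.append(s.tumor)
    for organ in s.organs_subtracted:
        parts.append(f"{organ}_subtracted")
    return "+".join(parts) or "parent"


def run_subset_study(train_cases: list[PreparedCase],
                     test_cases: list[PreparedCase],
                     subset_grid: list[SubsetSpec],
                     net_cfg: NetConfig, train_cfg: TrainConfig
                     ) -> tuple[dict[str, TrainedModel], pd.DataFrame,
                                pd.DataFrame]:
    """Returns (models, per-case DSC table, per-organ comparison table)."""
    specs = {"parent": SubsetSpec()}
    for s in subset_grid:
        specs[_subset_name(s)] = s

    models: dict[str, TrainedModel] = {}
    tables = []
    for name, spec in specs.items():
        model, _ = train_on_cases(train_cases, net_cfg, train_cfg, spec)
        models[name] = model
        preds = [predict_case(model, c) for c in test_cases]
        refs = [c.labels for c in test_cases]
        table = evaluate_cases(preds, refs)
        table.insert(0, "model", name)
        tables.append(table)
    dsc_table = pd.concat(tables, ignore_index=True)

    organs = sorted(dsc_table["organ"].unique())
    subset_names = [n for n in specs if n != "parent"]
    m = max(1, len(subset_names) * len(organs))
    rows = []
    parent_tbl = dsc_table[dsc_table["model"] == "parent"]
    for name in subset_names:
        sub_tbl = dsc_table[dsc_table["model"] == name]
        for organ in organs:
            a = parent_tbl.loc[parent_tbl["organ"] == organ, "dsc"].to_numpy()
            b = sub_tbl.loc[sub_tbl["organ"] == organ, "dsc"].to_numpy()
            if len(a) < 2 or len(b) < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
                continue
            cmp = compare_models(a, b, n_comparisons=m)
            rows.append({"model": name, "organ": organ,
                         "t": cmp.t_statistic, "p_one_sided": cmp.p_one_sided,
                         "adjusted_alpha": cmp.adjusted_alpha,
                         "significant": cmp.significant,
                         "significant_adjusted": cmp.significant_adjusted})
    return models, dsc_table, pd.DataFrame(rows)
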