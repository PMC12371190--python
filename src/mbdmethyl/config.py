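"""Pipeline configuration: documented defaults plus optional YAML overrides."""

from __future__ import annotations

import copy
from typing import Optional

import yaml

DEFAULTS = {
    "peaks": {
        # peak-call retention: fold-enrichment strictly > 4, p strictly < 0.01
        "fold_enrichment_min": 4.0,
        "peak_p_max": 0.01,
        # "more than 2 samples" support rule
        "min_support_samples": 3,
        "mean_coverage_min": 10.0,
        "nearest_gene_window": 100_000,
        "promoter_flank": 1_000,
        "shore_flank": 1_000,
    },
    "differential": {
        "dmr_p_max": 0.01,
        "dispersion_shrinkage": 0.3,
        "tissue_mode": "both",  # brain | blood | both
    },
    "biomarker": {
        "auc_min": 0.65,
        "cpg_min": 4,  # strict: kept regions need cpg_count > 4
        "max_subset_size": 3,
        "combo_cap": 20_000,
        "n_boot": 999,
    },
    "pca": {
        "scale": True,
        "n_components": 6,
        "pseudocount": 0.5,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[str] = None) -> dict:
    """Return the default config, deep-merged with a YAML file if given."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, override)
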