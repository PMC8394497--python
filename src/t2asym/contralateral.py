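"""Contralateral folding: pair mean / absolute difference feature table.

For every left/right region pair and every signal or texture feature f,
the analysis table carries two derived columns: the pair mean
``(f_L + f_R) / 2`` and the absolute contralateral difference
``|f_L - f_R|``. Volumes pass through per region, unfolded, and the
neuropsychological scores join unchanged. With the full 83-region atlas
(40 pairs) and the default 38-feature registry this yields
37 x 2 x 40 = 2960 contralateral signal/texture columns plus 83 volume
columns plus 8 neuropsychological columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from t2asym.features import default_registry


def _pair_features(registry) -> list:
    """The signal+texture features that get folded (37 with defaults)."""
    reg = registry if registry is not None else default_registry()
    return [d.name for d in reg if d.family in ("signal", "texture")]


def fold_contralateral(region_df: pd.DataFrame, atlas, registry=None) -> pd.Series:
    """Fold one subject's long-format region features into derived columns.

    Parameters
    ----------
    region_df : DataFrame
        Output of :func:`t2asym.features.extract_all` for one subject.
    atlas : RegionAtlas
    registry : list of FeatureDefinition, optional

    Returns
    -------
    Series indexed by column name: ``pair.feature.mean`` and
    ``pair.feature.absdiff`` for every pair and foldable feature, plus
    ``region.volume`` per region. If either member of a pair is missing a
    feature, both derived values for that feature are NaN.
    """
    feats = _pair_features(registry)
    wide = region_df.pivot_table(
        index="region", columns="feature", values="value", dropna=False, aggfunc="first"
    )
    out = {}
    for left, right in atlas.pairs:
        pair = atlas.pair_name(left)
        for f in feats:
            fl = wide.at[left, f] if (left in wide.index and f in wide) else np.nan
            fr = wide.at[right, f] if (right in wide.index and f in wide) else np.nan
            if np.isnan(fl) or np.isnan(fr):
                mean = absdiff = np.nan
            else:
                mean = (fl + fr) / 2.0
                absdiff = abs(fl - fr)
            out[f"{pair}.{f}.mean"] = mean
            out[f"{pair}.{f}.absdiff"] = absdiff
    if "volume" in (wide.columns if hasattr(wide, "columns") else []):
        for lab, name in sorted(atlas.regions.items()):
            out[f"{name}.volume"] = wide.at[lab, "volume"] if lab in wide.index else np.nan
    return pd.Series(out)


def build_manifest(atlas, registry=None, modes=("mean", "absdiff")) -> pd.DataFrame:
    """Deterministic manifest of every derived column.

    Columns: ``column, family, feature, mode, regions``. Contralateral
    entries come first (pair order, feature order, mean before absdiff),
    then the per-region volume columns.
    """
    reg = registry if registry is not None else default_registry()
    feats = {d.name: d.family for d in reg if d.family in ("signal", "texture")}
    rows = []
    for left, right in atlas.pairs:
        pair = atlas.pair_name(left)
        for f, fam in feats.items():
            for mode in modes:
                rows.append(
                    {
                        "column": f"{pair}.{f}.{mode}",
                        "family": fam,
                        "feature": f,
                        "mode": mode,
                        "regions": f"{atlas.regions[left]}|{atlas.regions[right]}",
                    }
                )
    if any(d.family == "volume" for d in reg):
        for lab, name in sorted(atlas.regions.items()):
            rows.append(
                {
                    "column": f"{name}.volume",
                    "family": "volume",
                    "feature": "volume",
                    "mode": "region",
                    "regions": name,
                }
            )
    return pd.DataFrame(rows)


def assemble_table(
    subject_region_dfs: dict,
    cohort: pd.DataFrame,
    atlas,
    registry=None,
) -> pd.DataFrame:
    """Build the analysis-ready subjects x features table.

    Parameters
    ----------
    subject_region_dfs : dict of subject_id -> long-format region features
    cohort : DataFrame
        Must contain ``subject_id`` and ``group``; any ``score_*`` columns
        join as neuropsychological features.

    Returns
    -------
    Wide DataFrame indexed by subject_id with a ``group`` column followed
    by contralateral/volume/neuropsych feature columns.
    """
    folded = pd.DataFrame(
        {sid: fold_contralateral(df, atlas, registry) for sid, df in subject_region_dfs.items()}
    ).T
    folded.index.name = "subject_id"
    meta = cohort.set_index("subject_id")
    score_cols = [c for c in meta.columns if c.startswith("score_")]
    table = pd.concat([meta[["group"]], folded, meta[score_cols]], axis=1)
    return table.loc[list(subject_region_dfs)]


def drop_sparse_columns(table: pd.DataFrame, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Drop feature columns missing in more than ``max_missing_frac`` of subjects."""
    feat = table.drop(columns=["group"], errors="ignore")
    keep = feat.columns[feat.isna().mean() <= max_missing_frac]
    cols = (["group"] if "group" in table else []) + list(keep)
    return table[cols]
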