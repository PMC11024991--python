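"""The 28-drug CiPA reference registry: free Cmax (nM), risk class, split.

Twelve drugs train the classifier (4 per risk class) and sixteen are held
out for testing (4 high / 7 intermediate / 5 low), following the CiPA
panel assignment used by the study protocol.
"""

from __future__ import annotations

import pandas as pd

_BUILTIN = [
    # name, cmax_nM, risk, split
    ("bepridil", 33.0, "high", "train"),
    ("dofetilide", 2.0, "high", "train"),
    ("sotalol", 1439.0, "high", "train"),
    ("quinidine", 3237.0, "high", "train"),
    ("cisapride", 2.6, "intermediate", "train"),
    ("chlorpromazine", 38.0, "intermediate", "train"),
    ("ondansetron", 139.0, "intermediate", "train"),
    ("terfenadine", 4.0, "intermediate", "train"),
    ("diltiazem", 122.0, "low", "train"),
    ("mexiletine", 4129.0, "low", "train"),
    ("ranolazine", 1948.2, "low", "train"),
    ("verapamil", 81.0, "low", "train"),
    ("azimilide", 70.0, "high", "test"),
    ("disopyramide", 742.0, "high", "test"),
    ("ibutilide", 100.0, "high", "test"),
    ("vandetanib", 255.4, "high", "test"),
    ("astemizole", 0.26, "intermediate", "test"),
    ("clarithromycin", 1206.0, "intermediate", "test"),
    ("clozapine", 71.0, "intermediate", "test"),
    ("domperidone", 19.0, "intermediate", "test"),
    ("droperidol", 6.33, "intermediate", "test"),
    ("pimozide", 0.431, "intermediate", "test"),
    ("risperidone", 1.81, "intermediate", "test"),
    ("loratadine", 0.45, "low", "test"),
    ("metoprolol", 1800.0, "low", "test"),
    ("nifedipine", 7.7, "low", "test"),
    ("nitrendipine", 3.02, "low", "test"),
    ("tamoxifen", 21.0, "low", "test"),
]

REGISTRY_COLUMNS = ["name", "cmax", "risk", "split"]


def builtin_registry() -> pd.DataFrame:
    return pd.DataFrame(_BUILTIN, columns=REGISTRY_COLUMNS)


def validate_registry(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate drug names: {dupes}")
    df = df.copy()
    df["cmax"] = pd.to_numeric(df["cmax"])
    if (df["cmax"] <= 0).any():
        raise ValueError("cmax must be positive (nM)")
    bad = set(df["risk"]) - {"high", "intermediate", "low"}
    if bad:
        raise ValueError(f"unknown risk labels: {sorted(bad)}")
    bad = set(df["split"]) - {"train", "test"}
    if bad:
        raise ValueError(f"unknown split values: {sorted(bad)}")
    return df


def load_registry(path=None) -> pd.DataFrame:
    """Builtin CiPA registry, or a custom CSV in the same dialect."""
    if path is None or path == "builtin":
        return builtin_registry()
    return validate_registry(pd.read_csv(path))
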