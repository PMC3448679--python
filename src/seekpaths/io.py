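"""Readers and writers for the package's plain-text table dialects.

* Query log — TSV, header ``user_id  day  query_text  cancers  page_id
  category``; ``cancers`` comma-joined, ``category`` a canonical token
  or ``NA``.
* Contacts — two-column TSV ``user_a  user_b``, undirected,
  deduplicated, no self-loops.
* Lexicon — CSV ``cancer,synonyms,incidence_per_100k,survival_5yr_pct,
  median_age_dx`` with ``|``-joined synonyms.
* Profiles — TSV with ``category_sequence`` and ``cancers``
  comma-joined.
* Ballots — CSV ``page_id,v1..v5``; sequences — one user per line,
  comma-joined category tokens; models and reports — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .hmm import CategoryHMM


def write_query_log(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_query_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    df["day"] = df["day"].astype(int)
    return df


def write_contacts(contacts: pd.DataFrame, path) -> None:
    contacts.to_csv(path, sep="\t", index=False)


def read_contacts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_lexicon(lexicon: pd.DataFrame, path) -> None:
    lexicon.to_csv(path, index=False)


def read_lexicon(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    out = profiles.copy()
    if "category_sequence" in out.columns:
        out["category_sequence"] = out["category_sequence"].apply(
            lambda s: ",".join(s) if isinstance(s, (list, tuple)) else s
        )
    out.to_csv(path, sep="\t", index=False)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "category_sequence" in df.columns:
        df["category_sequence"] = df["category_sequence"].astype(str).str.split(",")
    return df


def write_sequences(sequences, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            fh.write(",".join(seq) + "\n")


def read_sequences(path) -> list[list[str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(line.split(","))
    return out


def write_model(model: CategoryHMM, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1), encoding="utf-8")


def read_model(path) -> CategoryHMM:
    return CategoryHMM.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def write_ballots(ballots: pd.DataFrame, path) -> None:
    ballots.to_csv(path, index=False)


def read_ballots(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True), encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
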