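"""Bundled cancer lexicon.

Thirty-five common specific cancers with search synonyms and registry-style
epidemiological attributes: age-adjusted incidence per 100,000, age-adjusted
5-year relative survival (%), and median age at diagnosis (years). The
numeric values are rounded, registry-era US figures bundled as defaults for
simulation and worked examples; analyses of real logs should supply their
own lexicon CSV (see :mod:`seekpaths.io`).

No entry's name or synonym may occur, as a whole word or phrase, inside
another entry's terms — this keeps word-boundary query matching one-to-one
for templated queries (verified by the test suite).
"""

from __future__ import annotations

import pandas as pd

# name, |-joined synonyms, incidence_per_100k, survival_5yr_pct, median_age_dx
_ENTRIES = [
    ("breast cancer", "breast carcinoma|breast tumor", 124.0, 89.0, 61.0),
    ("prostate cancer", "prostate carcinoma|prostate tumor", 147.0, 99.0, 66.0),
    ("lung cancer", "lung carcinoma|lung tumor", 62.0, 17.0, 70.0),
    ("colon cancer", "colorectal cancer|bowel cancer", 45.0, 65.0, 68.0),
    ("melanoma", "skin melanoma|malignant melanoma", 21.0, 92.0, 63.0),
    ("bladder cancer", "bladder carcinoma|bladder tumor", 21.0, 77.0, 73.0),
    ("non-hodgkin lymphoma", "lymphoma|nhl", 19.0, 71.0, 66.0),
    ("kidney cancer", "renal cancer|renal cell carcinoma", 15.0, 73.0, 64.0),
    ("thyroid cancer", "thyroid carcinoma|thyroid tumor", 13.0, 98.0, 50.0),
    ("uterine cancer", "endometrial cancer|uterus cancer", 25.0, 82.0, 62.0),
    ("leukemia", "leukaemia|blood cancer", 13.0, 57.0, 66.0),
    ("pancreatic cancer", "pancreas cancer|pancreatic carcinoma", 12.0, 7.0, 70.0),
    ("ovarian cancer", "ovary cancer|ovarian carcinoma", 12.0, 45.0, 63.0),
    ("liver cancer", "hepatocellular carcinoma|hepatic cancer", 8.0, 17.0, 63.0),
    ("stomach cancer", "gastric cancer|stomach carcinoma", 7.0, 29.0, 69.0),
    ("brain cancer", "brain tumor|glioblastoma", 6.0, 33.0, 58.0),
    ("multiple myeloma", "myeloma|plasma cell myeloma", 6.0, 45.0, 69.0),
    ("esophageal cancer", "esophagus cancer|oesophageal cancer", 4.5, 19.0, 67.0),
    ("cervical cancer", "cervix cancer|cervical carcinoma", 7.5, 68.0, 49.0),
    ("laryngeal cancer", "larynx cancer|throat cancer", 3.3, 61.0, 65.0),
    ("oral cancer", "mouth cancer|tongue cancer", 11.0, 65.0, 62.0),
    ("testicular cancer", "testicle cancer|testis cancer", 5.5, 95.0, 33.0),
    ("hodgkin disease", "hodgkins disease", 2.7, 86.0, 38.0),
    ("gallbladder cancer", "biliary cancer", 1.1, 19.0, 72.0),
    ("bone cancer", "osteosarcoma|bone tumor", 0.9, 67.0, 42.0),
    ("mesothelioma", "pleural mesothelioma|asbestos cancer", 1.0, 10.0, 72.0),
    ("small intestine cancer", "duodenal cancer", 2.2, 66.0, 66.0),
    ("anal cancer", "anus cancer", 1.8, 66.0, 61.0),
    ("vulvar cancer", "vulva cancer", 2.5, 71.0, 68.0),
    ("vaginal cancer", "vagina cancer", 0.7, 49.0, 68.0),
    ("penile cancer", "penis cancer", 0.8, 67.0, 68.0),
    ("eye cancer", "ocular cancer|eye tumor", 0.9, 80.0, 61.0),
    ("salivary gland cancer", "parotid cancer", 1.3, 72.0, 64.0),
    ("thymus cancer", "thymoma|thymic carcinoma", 0.2, 71.0, 57.0),
    ("nasopharyngeal cancer", "nasopharynx cancer", 0.6, 61.0, 52.0),
]

LEXICON_COLUMNS = [
    "cancer",
    "synonyms",
    "incidence_per_100k",
    "survival_5yr_pct",
    "median_age_dx",
]


def default_lexicon() -> pd.DataFrame:
    """Return the bundled 35-cancer lexicon as a DataFrame.

    Columns follow the lexicon CSV dialect: ``cancer``, ``synonyms``
    (``|``-joined), ``incidence_per_100k``, ``survival_5yr_pct``,
    ``median_age_dx``.
    """
    return pd.DataFrame(_ENTRIES, columns=LEXICON_COLUMNS)


def lexicon_terms(lexicon: pd.DataFrame) -> dict[str, list[str]]:
    """Map each cancer name to all of its matchable terms (name first)."""
    out: dict[str, list[str]] = {}
    for row in lexicon.itertuples(index=False):
        syns = [s for s in str(row.synonyms).split("|") if s] if row.synonyms else []
        out[row.cancer] = [row.cancer, *syns]
    return out
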