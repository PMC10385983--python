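"""Code normalization and integer-token vocabularies.

Raw events become typed token strings in disjoint namespaces — ``DX:`` for
3-character ICD-10 diagnosis groups (after optional ICD-9 conversion),
``RX:`` for drug identifiers (after optional lexicon lookup), ``LAB:`` for
lab identifiers whose result flag marks an abnormal value.  A Vocabulary maps
tokens to 1-based integer ids (0 is reserved for padding) with patient-level
frequency counts; it is built on the training fold only, keeps only the most
frequently tested labs, and caps total size by dropping the rarest codes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .simulate import ABNORMAL_FLAGS, Encounter, LabEvent

__all__ = [
    "MappingTables",
    "Vocabulary",
    "to_diagnosis_group",
    "map_icd9",
    "map_drug",
    "filter_lab_events",
    "encounter_tokens",
    "build_vocabulary",
    "pack_sample",
]

log = logging.getLogger(__name__)

PAD = 0
DEFAULT_MAX_VOCAB = 30_000
DEFAULT_TOP_LABS = 89


def to_diagnosis_group(icd10_code: str) -> str:
    """First three characters of an ICD-10 code, upper-cased."""
    code = icd10_code.strip().upper()
    if len(code) < 3:
        raise ValueError(f"ICD-10 code too short: {icd10_code!r}")
    return code[:3]


def _norm_drug(name: str) -> str:
    return " ".join(name.split()).lower()


@dataclass
class MappingTables:
    """Lookup tables for ICD-9 to ICD-10 conversion and drug-name resolution."""

    icd9_to_icd10: dict[str, str] = field(default_factory=dict)
    drug_lexicon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.icd9_to_icd10 = {k.strip().upper(): v.strip().upper()
                              for k, v in self.icd9_to_icd10.items()}
        self.drug_lexicon = {_norm_drug(k): v.strip()
                             for k, v in self.drug_lexicon.items()}

    @classmethod
    def from_csv(cls, icd_path=None, drug_path=None) -> "MappingTables":
        import pandas as pd

        icd = {}
        if icd_path is not None:
            df = pd.read_csv(icd_path, dtype=str)
            icd = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        drugs = {}
        if drug_path is not None:
            df = pd.read_csv(drug_path, dtype=str)
            drugs = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return cls(icd, drugs)


def map_icd9(code: str, tables: MappingTables) -> str | None:
    return tables.icd9_to_icd10.get(code.strip().upper())


def map_drug(name: str, tables: MappingTables) -> str | None:
    """Case-insensitive, whitespace-normalized exact lookup; None on miss."""
    hit = tables.drug_lexicon.get(_norm_drug(name))
    if hit is None:
        log.debug("unmapped drug name: %r", name)
    return hit


def filter_lab_events(
    lab_events: list[LabEvent],
    keep_flags: frozenset[str] | set[str] = frozenset(ABNORMAL_FLAGS),
    top_k: int = DEFAULT_TOP_LABS,
    frequency: dict[str, int] | None = None,
) -> list[str]:
    """Lab ids of abnormally flagged events, restricted to the ``top_k`` most
    frequently tested labs when a population frequency table is given."""
    kept = [le.lab_id for le in lab_events if le.flag in keep_flags]
    if frequency is not None:
        ranked = sorted(frequency, key=lambda k: (-frequency[k], k))[:top_k]
        allowed = set(ranked)
        kept = [lab for lab in kept if lab in allowed]
    return kept


def encounter_tokens(enc: Encounter, tables: MappingTables | None = None) -> list[str]:
    """Typed tokens for one encounter (deduplicated, lexicographic order).

    With mapping tables, diagnosis codes found in the ICD-9 table are converted
    first and drug names are resolved through the lexicon (misses dropped);
    without tables, codes are taken as already-normalized ICD-10 / drug ids.
    Lab events survive only with an abnormal result flag; the top-k lab
    restriction is applied later, at vocabulary-building time.
    """
    tokens = set()
    for code in enc.dx_codes:
        if tables is not None:
            code = tables.icd9_to_icd10.get(code.strip().upper(), code)
        try:
            tokens.add("DX:" + to_diagnosis_group(code))
        except ValueError:
            log.debug("dropped malformed diagnosis code %r", code)
    for code in enc.rx_codes:
        if tables is not None and tables.drug_lexicon:
            mapped = map_drug(code, tables)
            if mapped is None:
                continue
            code = mapped
        tokens.add("RX:" + code.strip())
    for lab in filter_lab_events(enc.lab_events):
        tokens.add("LAB:" + lab)
    return sorted(tokens)


@dataclass
class Vocabulary:
    token_of: dict[str, int]
    code_of: dict[int, str]
    frequency: dict[int, int]          # token id -> number of distinct patients
    max_size: int = DEFAULT_MAX_VOCAB

    def __len__(self) -> int:
        return len(self.token_of)

    def __contains__(self, code: str) -> bool:
        return code in self.token_of

    @property
    def n_tokens(self) -> int:
        """Highest assigned id (embedding tables need n_tokens + 1 rows)."""
        return len(self.token_of)

    def to_json(self, path) -> None:
        rows = [{"code": c, "token": t, "frequency": self.frequency[t]}
                for c, t in sorted(self.token_of.items(), key=lambda kv: kv[1])]
        with open(path, "w") as fh:
            json.dump({"max_size": self.max_size, "tokens": rows}, fh, indent=0)

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        with open(path) as fh:
            obj = json.load(fh)
        token_of = {r["code"]: r["token"] for r in obj["tokens"]}
        freq = {r["token"]: r["frequency"] for r in obj["tokens"]}
        return cls(token_of, {t: c for c, t in token_of.items()},
                   freq, obj["max_size"])


def build_vocabulary(
    train_samples,
    max_size: int = DEFAULT_MAX_VOCAB,
    top_k_labs: int = DEFAULT_TOP_LABS,
) -> Vocabulary:
    """Patient-level token frequencies over the training fold.

    Lab tokens beyond the ``top_k_labs`` most frequently tested labs are
    dropped, then the vocabulary is capped at ``max_size`` by discarding the
    lowest-frequency codes (ties broken lexicographically).  Ids are assigned
    1..V in decreasing frequency so truncation at serving time is stable.
    """
    patients_of: dict[str, set[str]] = {}
    for s in train_samples:
        for _, tokens in s.visits:
            for tok in tokens:
                patients_of.setdefault(tok, set()).add(s.patient_id)
    freq = {tok: len(pids) for tok, pids in patients_of.items()}

    lab_tokens = [t for t in freq if t.startswith("LAB:")]
    keep_labs = set(sorted(lab_tokens, key=lambda t: (-freq[t], t))[:top_k_labs])
    codes = [t for t in freq if not t.startswith("LAB:") or t in keep_labs]
    codes.sort(key=lambda t: (-freq[t], t))
    codes = codes[:max_size]

    token_of = {c: i + 1 for i, c in enumerate(codes)}  # 0 reserved for padding
    return Vocabulary(token_of, {i: c for c, i in token_of.items()},
                      {token_of[c]: freq[c] for c in codes}, max_size)


def pack_sample(sample, vocab: Vocabulary) -> list[list[int]]:
    """Integer token lists per visit, date-ordered, out-of-vocabulary dropped.

    Visits that lose all their tokens are retained as empty lists (the model
    treats them as information-free timesteps); a sample with no in-vocabulary
    token anywhere is rejected.
    """
    packed = []
    for _, tokens in sorted(sample.visits, key=lambda v: v[0]):
        ids = [vocab.token_of[t] for t in sorted(set(tokens)) if t in vocab.token_of]
        packed.append(ids)
    if not any(packed):
        raise ValueError(f"sample {sample.patient_id} has no in-vocabulary tokens")
    return packed
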