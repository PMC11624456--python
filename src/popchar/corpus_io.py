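"""Readers and writers for bibliographic and annotation formats.

Abstracts come in as MEDLINE flat files (PMID/TI/AB/DP/LA tags, parsed via
Bio.Medline) or PubMed XML exports (lxml). Records without an abstract are
skipped and counted, never silently dropped. Results go out as one JSON
object per line (streamable, diff-friendly); gold annotations are
hand-editable tab-separated text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import Medline
from lxml import etree

from .model import (
    AbstractRecord,
    AgeGroup,
    Characteristic,
    GoldAnnotation,
    MentionSpan,
    OffenderCategory,
    SexCategory,
    StandardizedValue,
)
from .util import ValidationError, normalize_ws

logger = logging.getLogger(__name__)


@dataclass
class Corpus:
    """A list of abstracts plus the number of source records skipped for
    lacking an abstract."""

    records: list[AbstractRecord] = field(default_factory=list)
    skipped: int = 0

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, index):
        return self.records[index]


def _check_unique(records: Sequence[AbstractRecord]) -> None:
    seen: set[str] = set()
    for record in records:
        if record.pmid in seen:
            raise ValidationError(f"duplicate PMID {record.pmid!r} in corpus")
        seen.add(record.pmid)


def _year_from_dp(dp: Optional[str]) -> Optional[int]:
    if not dp:
        return None
    import re

    m = re.match(r"\s*(\d{4})", dp)
    return int(m.group(1)) if m else None


def read_medline(path: str | Path) -> Corpus:
    """Read a MEDLINE flat-format file into a corpus.

    Records without an AB field are skipped and counted; a duplicate PMID
    raises naming the offender.
    """
    path = Path(path)
    corpus = Corpus()
    with open(path, encoding="utf-8") as handle:
        for rec in Medline.parse(handle):
            pmid = rec.get("PMID")
            if not pmid:
                logger.warning("%s: record without PMID skipped", path.name)
                corpus.skipped += 1
                continue
            abstract = rec.get("AB")
            if not abstract or not abstract.strip():
                logger.warning("%s: PMID %s has no abstract; skipped", path.name, pmid)
                corpus.skipped += 1
                continue
            language = rec.get("LA")
            if isinstance(language, list):
                language = language[0] if language else "eng"
            corpus.records.append(
                AbstractRecord(
                    pmid=pmid,
                    text=abstract,
                    year=_year_from_dp(rec.get("DP")),
                    title=rec.get("TI"),
                    language=language or "eng",
                )
            )
    _check_unique(corpus.records)
    missing_year = sum(1 for r in corpus.records if r.year is None)
    if missing_year:
        logger.info(
            "%s: %d records without a publication year (kept for extraction, "
            "excluded from trend analytics)", path.name, missing_year,
        )
    return corpus


def write_medline(records: Sequence[AbstractRecord], path: str | Path) -> None:
    """Write records as MEDLINE flat format (PMID/TI/AB/DP/LA tags)."""
    lines: list[str] = []
    for record in records:
        lines.append(f"PMID- {record.pmid}")
        if record.title:
            lines.append(f"TI  - {record.title}")
        lines.append(f"AB  - {record.text}")
        if record.year is not None:
            lines.append(f"DP  - {record.year}")
        lines.append(f"LA  - {record.language}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_pubmed_xml(path: str | Path, date_policy: str = "earliest") -> Corpus:
    """Read a PubMed XML export (PubmedArticleSet).

    Structured abstracts (multiple AbstractText sections) are concatenated
    with single spaces. The publication year is, by default, the earliest
    Year found in any PubDate element of the article; pass
    ``date_policy="journal"`` to use the journal-issue PubDate only (which
    date field defines the publication year is a corpus-construction
    choice, so it is exposed as a flag).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise OSError(f"{path.name}: XML parse failure: {exc}") from exc
    corpus = Corpus()
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//MedlineCitation/PMID")
        sections = [
            normalize_ws("".join(node.itertext()))
            for node in article.iter("AbstractText")
        ]
        abstract = " ".join(s for s in sections if s)
        if not pmid:
            corpus.skipped += 1
            continue
        if not abstract:
            logger.warning("%s: PMID %s has no abstract; skipped", path.name, pmid)
            corpus.skipped += 1
            continue
        if date_policy == "journal":
            date_nodes = article.findall(".//JournalIssue/PubDate")
        else:
            date_nodes = article.findall(".//PubDate")
        years = []
        for node in date_nodes:
            year_text = node.findtext("Year") or ""
            if year_text.strip().isdigit():
                years.append(int(year_text))
            else:
                medline_date = node.findtext("MedlineDate") or ""
                import re

                m = re.search(r"\b(\d{4})\b", medline_date)
                if m:
                    years.append(int(m.group(1)))
        corpus.records.append(
            AbstractRecord(
                pmid=pmid,
                text=abstract,
                year=min(years) if years else None,
                title=article.findtext(".//ArticleTitle"),
                language=article.findtext(".//Language") or "eng",
            )
        )
    _check_unique(corpus.records)
    return corpus


# ---------------------------------------------------------------------------
# Gold annotations (TSV)

_AGE_LABELS = {g.value for g in AgeGroup}
_SEX_LABELS = {c.value for c in SexCategory}
_OFFENDER_LABELS = {c.value for c in OffenderCategory}


def _validate_value(kind: Characteristic, label: str, attribute: Optional[str],
                    where: str) -> StandardizedValue:
    if kind is Characteristic.AGE and label not in _AGE_LABELS:
        raise ValidationError(f"{where}: unknown age band {label!r}")
    if kind is Characteristic.SEX and label not in _SEX_LABELS:
        raise ValidationError(f"{where}: unknown sex category {label!r}")
    if kind is Characteristic.OFFENDER_TYPE and label not in _OFFENDER_LABELS:
        raise ValidationError(f"{where}: unknown offender category {label!r}")
    if kind is not Characteristic.OFFENDER_TYPE:
        attribute = None
    try:
        return StandardizedValue(kind, label, attribute)
    except ValueError as exc:
        raise ValidationError(f"{where}: {exc}") from exc


def read_gold(path: str | Path) -> dict[str, GoldAnnotation]:
    """Read a gold file: ``pmid <TAB> CHARACTERISTIC <TAB> label [<TAB>
    attribute]``. Duplicate (pmid, value) lines collapse; unknown kinds or
    labels raise naming the line."""
    path = Path(path)
    values: dict[str, set[StandardizedValue]] = {}
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path.name}:{lineno}: expected pmid<TAB>kind<TAB>label"
            )
        pmid = parts[0].strip()
        where = f"{path.name}:{lineno}"
        try:
            kind = Characteristic(parts[1].strip())
        except ValueError as exc:
            raise ValidationError(
                f"{where}: unknown characteristic {parts[1]!r}"
            ) from exc
        attribute = parts[3].strip() if len(parts) > 3 and parts[3].strip() else None
        value = _validate_value(kind, parts[2].strip(), attribute, where)
        values.setdefault(pmid, set()).add(value)
    return {
        pmid: GoldAnnotation(pmid, frozenset(vals))
        for pmid, vals in values.items()
    }


def write_gold(annotations: Sequence[GoldAnnotation], path: str | Path) -> None:
    lines = []
    for ann in annotations:
        for value in sorted(ann.values, key=lambda v: v.sort_key):
            fields = [ann.pmid, value.kind.value, value.label]
            if value.attribute:
                fields.append(value.attribute)
            lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# JSON-lines results

def _mention_to_json(m: MentionSpan) -> dict:
    out = {
        "kind": m.characteristic.value,
        "surface": m.surface,
        "start": m.start,
        "end": m.end,
        "rule": m.rule_id,
    }
    if m.low is not None:
        out["low"] = m.low
        out["high"] = m.high
    return out


def _value_to_json(v: StandardizedValue) -> dict:
    out = {"kind": v.kind.value, "label": v.label}
    if v.attribute:
        out["attribute"] = v.attribute
    return out


def write_results(
    path: str | Path,
    records: Sequence[AbstractRecord],
    mentions: Sequence[Sequence[MentionSpan]],
    values: Sequence[frozenset[StandardizedValue]],
) -> None:
    """One JSON object per abstract: pmid, year, text, raw mentions and the
    deduplicated standardized values."""
    with open(path, "w", encoding="utf-8") as handle:
        for record, ms, vs in zip(records, mentions, values):
            handle.write(
                json.dumps(
                    {
                        "pmid": record.pmid,
                        "year": record.year,
                        "text": record.text,
                        "mentions": [_mention_to_json(m) for m in ms],
                        "values": sorted(
                            (_value_to_json(v) for v in vs),
                            key=lambda d: (d["kind"], d["label"], d.get("attribute", "")),
                        ),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_results(path: str | Path):
    """Yield (AbstractRecord, mentions, values) triples from a result file."""
    out = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            record = AbstractRecord(
                pmid=obj["pmid"], text=obj["text"], year=obj.get("year")
            )
            mentions = [
                MentionSpan(
                    Characteristic(m["kind"]), m["surface"], m["start"],
                    m["end"], m["rule"], m.get("low"), m.get("high"),
                )
                for m in obj.get("mentions", [])
            ]
            values = frozenset(
                StandardizedValue(
                    Characteristic(v["kind"]), v["label"], v.get("attribute")
                )
                for v in obj.get("values", [])
            )
            out.append((record, mentions, values))
    return out
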