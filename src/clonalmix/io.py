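"""Case-table readers/writers and the packaged contralateral-breast dataset.

The on-disk exchange format is a plain TSV with header

    case_id  locus_id  gene_label  p  in_tumor1  in_tumor2

one row per observed locus. A locus mutated in both tumors (1/1) is shared;
mutated in exactly one (1/0 or 0/1) is private; 0/0 is not informative data
and is rejected. Cases with no loci can be declared with a row whose
locus_id is ``-`` and p is ``-`` (both tumor flags 0 are allowed only on
such declaration rows).

The packaged dataset transcribes a published study of 49 women with presumed
contralateral breast cancer sequenced on a breast-cancer gene panel: per
tumor-pair mutation counts, match counts, and the occurrence probabilities
of the matched mutations (0.137 for the PIK3CA H1047R hotspot; below 1/1000
for the rare matches). Probabilities not printed in the source table — rare
matched loci and all private loci — default to 1e-3, exposed as knobs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .estimate import FitResult
from .model import PRIVATE, SHARED, CasePair, MutationLocus

__all__ = [
    "CaseTableRecord",
    "CaseTableError",
    "read_case_table",
    "write_case_table",
    "contralateral_breast_fixture",
    "fit_result_to_dict",
    "write_fit_json",
    "STUDY_COUNTS",
    "STUDY_MATCHES",
]

HEADER = ["case_id", "locus_id", "gene_label", "p", "in_tumor1", "in_tumor2"]

SCHEMA_VERSION = 1

#: Marker used on rows declaring a case with no observed mutations.
EMPTY_MARK = "-"


class CaseTableError(ValueError):
    """Malformed case table; message carries the offending line number."""


@dataclass(frozen=True)
class CaseTableRecord:
    """One parsed TSV row (one locus of one case)."""

    case_id: str
    locus_id: str
    gene_label: str
    p: float
    in_tumor1: int
    in_tumor2: int

    @property
    def status(self) -> str:
        return SHARED if (self.in_tumor1 and self.in_tumor2) else PRIVATE


def _parse_row(row: dict, lineno: int) -> CaseTableRecord | None:
    case_id = row["case_id"].strip()
    locus_id = row["locus_id"].strip()
    if not case_id:
        raise CaseTableError(f"line {lineno}: empty case_id")
    try:
        t1 = int(row["in_tumor1"])
        t2 = int(row["in_tumor2"])
    except (TypeError, ValueError):
        raise CaseTableError(
            f"line {lineno}: tumor flags must be 0/1, got "
            f"{row['in_tumor1']!r}/{row['in_tumor2']!r}"
        ) from None
    if t1 not in (0, 1) or t2 not in (0, 1):
        raise CaseTableError(f"line {lineno}: tumor flags must be 0/1")
    if locus_id == EMPTY_MARK:
        if t1 or t2:
            raise CaseTableError(
                f"line {lineno}: empty-case declaration row must have both "
                "tumor flags 0"
            )
        return None
    if t1 == 0 and t2 == 0:
        raise CaseTableError(
            f"line {lineno}: locus {locus_id!r} mutated in neither tumor is "
            "not informative data"
        )
    try:
        p = float(row["p"])
    except (TypeError, ValueError):
        raise CaseTableError(
            f"line {lineno}: malformed probability {row['p']!r}"
        ) from None
    if not (0.0 < p < 1.0):
        raise CaseTableError(
            f"line {lineno}: occurrence probability must lie strictly in "
            f"(0, 1), got {p}"
        )
    return CaseTableRecord(
        case_id=case_id,
        locus_id=locus_id,
        gene_label=row.get("gene_label", "").strip(),
        p=p,
        in_tumor1=t1,
        in_tumor2=t2,
    )


def read_case_table(path) -> list[CasePair]:
    """Read a TSV case table, validating every row.

    Cases are returned in file order; loci keep file order within a case.
    Duplicate (case_id, locus_id) pairs, probabilities outside (0, 1) and
    0/0 tumor flags are hard errors naming the line.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise CaseTableError("empty file: no header")
        if [f.strip() for f in reader.fieldnames] != HEADER:
            raise CaseTableError(
                f"bad header {reader.fieldnames!r}; expected {HEADER!r}"
            )
        loci_by_case: dict[str, list[MutationLocus]] = {}
        seen: set[tuple[str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            rec = _parse_row(row, lineno)
            if rec is None:  # declaration of a case without mutations
                loci_by_case.setdefault(row["case_id"].strip(), [])
                continue
            key = (rec.case_id, rec.locus_id)
            if key in seen:
                raise CaseTableError(
                    f"line {lineno}: duplicate locus {rec.locus_id!r} for "
                    f"case {rec.case_id!r}"
                )
            seen.add(key)
            loci_by_case.setdefault(rec.case_id, []).append(
                MutationLocus(locus_id=rec.locus_id, p=rec.p, status=rec.status)
            )
    return [CasePair(case_id=cid, loci=loci) for cid, loci in loci_by_case.items()]


def write_case_table(cases: Iterable[CasePair], path) -> None:
    """Write cases back to TSV (inverse of :func:`read_case_table`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HEADER)
        for case in cases:
            if not case.loci:
                writer.writerow([case.case_id, EMPTY_MARK, "", EMPTY_MARK, 0, 0])
                continue
            for locus in case.loci:
                t1, t2 = (1, 1) if locus.shared else (1, 0)
                writer.writerow(
                    [case.case_id, locus.locus_id, "", f"{locus.p:.6g}", t1, t2]
                )


# ---------------------------------------------------------------------------
# Packaged study data: 49 contralateral breast cancer cases.
#
# Per case: (mutations in tumor 1, mutations in tumor 2, number of matches).
# Case ids are the study's patient numbers (not consecutive).
STUDY_COUNTS: dict[str, tuple[int, int, int]] = {
    "1": (9, 7, 0), "2": (3, 3, 0), "3": (2, 7, 0), "4": (8, 10, 0),
    "6": (6, 5, 0), "8": (6, 2, 1), "9": (2, 3, 0), "12": (14, 3, 0),
    "13": (3, 3, 0), "15": (8, 5, 0), "16": (10, 8, 0), "17": (6, 8, 0),
    "18": (8, 2, 0), "21": (4, 3, 0), "23": (10, 4, 0), "24": (4, 3, 0),
    "25": (4, 6, 0), "26": (6, 5, 0), "27": (4, 5, 0), "29": (3, 1, 0),
    "30": (6, 5, 0), "31": (6, 5, 0), "32": (5, 4, 0), "33": (6, 4, 0),
    "35": (5, 4, 0), "36": (3, 4, 3), "38": (8, 2, 0), "40": (10, 1, 0),
    "41": (0, 9, 0), "43": (4, 4, 0), "44": (9, 21, 0), "45": (3, 4, 0),
    "48": (2, 3, 2), "52": (5, 7, 0), "56": (2, 5, 0), "58": (3, 4, 0),
    "59": (2, 3, 0), "62": (4, 4, 0), "63": (3, 9, 1), "64": (5, 4, 0),
    "66": (33, 3, 0), "67": (4, 1, 1), "70": (5, 2, 0), "71": (3, 1, 0),
    "72": (1, 3, 0), "74": (2, 1, 0), "75": (4, 3, 1), "76": (7, 5, 0),
    "77": (3, 1, 0),
}

#: Matched mutations with their printed occurrence probabilities; ``None``
#: marks loci printed only as "below 1/1000".
STUDY_MATCHES: dict[str, list[tuple[str, float | None]]] = {
    "8": [("ARID1A E250fs", None)],
    "36": [("CDH1 S111fs", None), ("TBX3 T267fs", None), ("EPPK1 R2337H", None)],
    "48": [("MLH3 M346R", None), ("MAP3K1 R248*", None)],
    "63": [("PIK3CA H1047R", 0.137)],
    "67": [("PIK3CA H1047R", 0.137)],
    "75": [("PIK3CA H1047R", 0.137)],
}

#: Hotspot probability printed for the PIK3CA H1047R matches.
PIK3CA_P = 0.137


def contralateral_breast_fixture(
    rare_match_p: float = 1e-3, private_p: float = 1e-3
) -> list[CasePair]:
    """Build the packaged 49-case contralateral breast cancer dataset.

    Matched loci printed "below 1/1000" get ``rare_match_p`` (the printed
    upper bound by default); private loci, whose probabilities the source
    does not print, get ``private_p``. Unmatched mutations are materialized
    as anonymous private loci to reach the per-tumor totals — the likelihood
    depends on private loci only through their count and probability.
    """
    cases = []
    for case_id, (n1, n2, n_match) in STUDY_COUNTS.items():
        loci: list[MutationLocus] = []
        matches = STUDY_MATCHES.get(case_id, [])
        assert len(matches) == n_match
        for gene, p in matches:
            loci.append(
                MutationLocus(
                    locus_id=gene,
                    p=rare_match_p if p is None else p,
                    status=SHARED,
                )
            )
        n_private = (n1 - n_match) + (n2 - n_match)
        for k in range(1, n_private + 1):
            loci.append(
                MutationLocus(locus_id=f"L{k}", p=private_p, status=PRIVATE)
            )
        cases.append(CasePair(case_id=case_id, loci=loci))
    return cases


def contralateral_breast_path():
    """Filesystem path of the packaged study TSV (default p assignments)."""
    import importlib.resources

    return importlib.resources.files("clonalmix") / "data" / "contralateral_breast.tsv"


def fit_result_to_dict(fit: FitResult) -> dict:
    """JSON-ready summary of one fit."""
    return {
        "method": fit.method,
        "pi": fit.params.pi,
        "mu": fit.params.mu,
        "sigma": fit.params.sigma,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "boundary": fit.boundary,
        "n_iter": fit.n_iter,
        "posteriors": [
            {"case_id": p.case_id, "w": p.w} for p in fit.posteriors
        ],
    }


def write_fit_json(fits: Sequence[FitResult], path, extra: dict | None = None) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "fits": [fit_result_to_dict(f) for f in fits],
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
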