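"""Three-criterion graded occupancy classification.

A (reader, histone mark) pair within one domain class is graded by how many
of three association criteria hold:

  C1  Pearson correlation of percentile signals  r >= 0.300
  C2  fraction of reader peaks significantly overlapping the mark >= 30%
  C3  overlap detected by heatmap (profile-matrix coverage call)

grade = number of satisfied criteria: 3 = prominent, 2 = detectable,
1 = weak, 0 = none.  Thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

GRADE_LABELS = {0: "none", 1: "weak", 2: "detectable", 3: "prominent"}

DEFAULT_R0 = 0.300
DEFAULT_F0 = 0.30


@dataclass
class AssociationResult:
    reader: str
    mark: str
    domain_class: str
    r: float
    sig_fraction: float
    heatmap_flag: bool
    grade: int
    label: str


def grade_association(r: float, sig_fraction: float, heatmap_flag: bool,
                      r0: float = DEFAULT_R0, f0: float = DEFAULT_F0,
                      reader: str = "", mark: str = "",
                      domain_class: str = "arm") -> AssociationResult:
    """Grade one reader x mark x domain-class triple.

    Raises on out-of-range inputs (r outside [-1, 1], fraction outside [0, 1]).
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    if not 0.0 <= sig_fraction <= 1.0:
        raise ValueError(f"significant-overlap fraction out of range: {sig_fraction}")
    satisfied = int(r >= r0) + int(sig_fraction >= f0) + int(bool(heatmap_flag))
    return AssociationResult(reader, mark, domain_class, r, sig_fraction,
                             bool(heatmap_flag), satisfied, GRADE_LABELS[satisfied])


def write_grades_tsv(results: list[AssociationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("reader\tmark\tdomain_class\tr\tsig_fraction\theatmap_flag\tgrade\tlabel\n")
        for a in results:
            fh.write(f"{a.reader}\t{a.mark}\t{a.domain_class}\t{a.r:.4f}\t"
                     f"{a.sig_fraction:.4f}\t{int(a.heatmap_flag)}\t{a.grade}\t{a.label}\n")
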