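import numpy as np
import pytest

from rhdtype.alleles import load_allele_db
from rhdtype.genemodel import build_synthetic_reference
from rhdtype.pipeline import run_panel
from rhdtype.primers import Primer, PrimerRole, load_exon_assays, load_ssp_assays, revcomp
from rhdtype.simulate import make_eqa_panel
from rhdtype.ssp import Assay

MODEL_SEED = 1
RUN_SEED = 1


@pytest.fixture(scope="session")
def db():
    return load_allele_db()


@pytest.fixture(scope="session")
def model():
    return build_synthetic_reference(seed=MODEL_SEED)


@pytest.fixture(scope="session")
def panel(model, db):
    return make_eqa_panel(model, db)


@pytest.fixture(scope="session")
def ssp_assays():
    return [Assay.from_def(d) for d in load_ssp_assays()]


@pytest.fixture(scope="session")
def exon_assays():
    return load_exon_assays()


@pytest.fixture(scope="session")
def study_run(panel, model, db, ssp_assays, exon_assays):
    """Full study-mode run of the proficiency panel (reports, summary)."""
    return run_panel(panel, model, db, ssp_assays, exon_assays, mode="study", seed=RUN_SEED)


@pytest.fixture(scope="session")
def routine_run(panel, model, db, ssp_assays, exon_assays):
    return run_panel(panel, model, db, ssp_assays, exon_assays, mode="routine", seed=RUN_SEED)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive in-silico PCR scan


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_amplicon(template, fwd, rev, max_len=1500, budget=0):
    """Naive reference implementation: enumerate every start position on
    both strands for both primers, apply the 3'-exact-match rule, and pick
    the shortest (then leftmost) convergent product."""
    if not template:
        return None
    t = template.upper()
    n = len(t)

    def plus_hits(core):
        L = len(core)
        return [
            i
            for i in range(n - L + 1)
            if t[i + L - 1] == core[-1] and _mismatches(t[i : i + L - 1], core[:-1]) <= budget
        ]

    def minus_hits(core):
        rc = revcomp(core)
        L = len(core)
        return [
            i
            for i in range(n - L + 1)
            if t[i] == rc[0] and _mismatches(t[i + 1 : i + L], rc[1:]) <= budget
        ]

    candidates = []
    for left, right, flip in ((fwd, rev, False), (rev, fwd, True)):
        for a in plus_hits(left.core):
            for b in minus_hits(right.core):
                end = b + len(right.core)
                length = end - a
                if a <= b and length <= max_len and length >= max(len(left.core), len(right.core)):
                    seg = t[a:end]
                    if flip:
                        product = right.tail + revcomp(seg) + revcomp(left.tail)
                    else:
                        product = left.tail + seg + revcomp(right.tail)
                    candidates.append((length, a, product))
    if not candidates:
        return None
    return min(candidates)[2]


@pytest.fixture(scope="session")
def pcr_oracle():
    return brute_force_amplicon


def random_primer(rng: np.random.Generator, length: int, primer_id="p") -> Primer:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return Primer(primer_id, seq, 0.25, PrimerRole.CONSENSUS)


@pytest.fixture(scope="session")
def make_random_primer():
    return random_primer
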