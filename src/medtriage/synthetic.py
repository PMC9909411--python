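"""Seeded synthetic corpora with the statistical shape of real OHC data.

Tokens are opaque strings ("d3t017" from department 3's vocabulary,
"sht102" from the shared vocabulary) — the pipeline is language-agnostic
once text is segmented, so no natural language is needed to exercise any
stage. Complaint lengths follow a lognormal chosen to match a heavily
right-skewed length distribution (default median ~50 tokens, mean ~89).
``separation`` controls how department-specific the vocabulary is: 1.0 gives
disjoint vocabularies per department, 0.0 makes departments statistically
indistinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .corpus import ComplaintRecord, Corpus, PhysicianRecord


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    n_departments: int = 8
    diseases_per_department: int = 1
    n_patients: int = 1430
    physicians_per_department: int = 8
    vocab_shared: int = 200
    vocab_per_department: int = 60
    separation: float = 0.7
    length_log_mean: float = math.log(50.0)  # median ~50 tokens
    length_log_sigma: float = 1.07           # mean ~50*exp(sigma^2/2) ~ 88.6
    reply_length_shape: float = 2.0
    reply_length_scale: float = 30.0         # mean reply ~60 characters
    voice_duration_shape: float = 2.0
    voice_duration_scale: float = 8.0        # mean voice message ~16 s
    replies_per_patient: int = 3
    extra_disease_first_department: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_departments, self.diseases_per_department, self.n_patients,
               self.physicians_per_department, self.vocab_shared,
               self.vocab_per_department) < 1:
            raise ConfigError("all counts must be >= 1")
        if not 0.0 <= self.separation <= 1.0:
            raise ConfigError("separation must be in [0, 1]")


#: Reference-scale preset for recommendation experiments: a single-department
#: pool resembling 63 physicians serving 1,430 patients.
def recommendation_preset(seed: int = 0, n_patients: int = 1430,
                          n_physicians: int = 63) -> SyntheticConfig:
    return SyntheticConfig(
        n_departments=1,
        diseases_per_department=4,
        n_patients=n_patients,
        physicians_per_department=n_physicians,
        vocab_per_department=80,
        separation=0.6,  # within-department disease clusters spread the cosines
        extra_disease_first_department=False,
        seed=seed,
    )


def guidance_preset(seed: int = 0, n_patients: int = 2000,
                    separation: float = 0.7,
                    length_log_mean: float = math.log(50.0),
                    length_log_sigma: float = 1.07) -> SyntheticConfig:
    """Eight departments, nine diseases — the triage study's label structure."""
    return SyntheticConfig(
        n_departments=8,
        diseases_per_department=1,
        n_patients=n_patients,
        physicians_per_department=2,
        separation=separation,
        length_log_mean=length_log_mean,
        length_log_sigma=length_log_sigma,
        extra_disease_first_department=True,
        seed=seed,
    )


def generate_corpus(config: SyntheticConfig) -> Corpus:
    """Draw a fully reproducible corpus from the configured distributions.

    Patients get departments uniformly; token counts are lognormal (floored
    at 2); each token comes from the department vocabulary with probability
    ``separation`` and from the shared vocabulary otherwise. Every patient is
    linked to a physician of its department, whose consulted texts are
    exactly its patients' complaints. Reply lengths and voice durations are
    gamma draws with a per-physician lognormal scale multiplier, so that
    physicians differ systematically in how much they write and speak.
    """
    rng = np.random.default_rng(config.seed)
    D = config.n_departments
    departments = [f"dept_{d}" for d in range(D)]

    diseases: dict[str, list[str]] = {
        dep: [f"disease_{d}_{k}" for k in range(config.diseases_per_department)]
        for d, dep in enumerate(departments)
    }
    if config.extra_disease_first_department:
        diseases[departments[0]].append(f"disease_0_{config.diseases_per_department}")

    shared_vocab = [f"sht{i:03d}" for i in range(config.vocab_shared)]
    dept_vocab = {
        dep: [f"d{d}t{i:03d}" for i in range(config.vocab_per_department)]
        for d, dep in enumerate(departments)
    }

    physicians_by_dept: dict[str, list[str]] = {}
    phys_meta: list[tuple[str, str]] = []
    pid = 0
    for dep in departments:
        ids = []
        for _ in range(config.physicians_per_department):
            pid += 1
            ids.append(f"phys_{pid:03d}")
            phys_meta.append((f"phys_{pid:03d}", dep))
        physicians_by_dept[dep] = ids

    complaints: list[ComplaintRecord] = []
    texts_by_physician: dict[str, list[str]] = {p: [] for p, _ in phys_meta}
    patients_by_physician: dict[str, int] = {p: 0 for p, _ in phys_meta}

    # each disease owns a round-robin slice of its department's vocabulary, so
    # complaints cluster by disease within a department the way real symptom
    # descriptions do
    disease_vocab: dict[str, list[str]] = {}
    for dep in departments:
        k = len(diseases[dep])
        for j, dis in enumerate(diseases[dep]):
            disease_vocab[dis] = dept_vocab[dep][j::k]

    dept_idx = rng.integers(0, D, size=config.n_patients)
    lengths = np.maximum(
        2, np.round(rng.lognormal(config.length_log_mean, config.length_log_sigma,
                                  size=config.n_patients)).astype(int)
    )
    for i in range(config.n_patients):
        dep = departments[dept_idx[i]]
        disease = diseases[dep][rng.integers(0, len(diseases[dep]))]
        dvocab = disease_vocab[disease]
        L = int(lengths[i])
        from_dept = rng.random(L) < config.separation
        tokens = [
            dvocab[rng.integers(0, len(dvocab))]
            if f
            else shared_vocab[rng.integers(0, config.vocab_shared)]
            for f in from_dept
        ]
        text = " ".join(tokens)
        phys = physicians_by_dept[dep][rng.integers(0, len(physicians_by_dept[dep]))]
        patient_id = f"pat_{i + 1:05d}"
        complaints.append(
            ComplaintRecord(
                patient_id=patient_id,
                text=text,
                disease=disease,
                department=dep,
                consulted_physician_id=phys,
            )
        )
        texts_by_physician[phys].append(text)
        patients_by_physician[phys] += 1

    physicians: list[PhysicianRecord] = []
    for phys_id, dep in phys_meta:
        n_replies = max(1, config.replies_per_patient * patients_by_physician[phys_id])
        text_mult = rng.lognormal(0.0, 0.5)
        voice_mult = rng.lognormal(0.0, 0.5)
        reply_lengths = np.round(
            rng.gamma(config.reply_length_shape,
                      config.reply_length_scale * text_mult, size=n_replies)
        ).astype(int)
        voice_durations = rng.gamma(config.voice_duration_shape,
                                    config.voice_duration_scale * voice_mult,
                                    size=n_replies)
        physicians.append(
            PhysicianRecord(
                physician_id=phys_id,
                name=f"Physician {phys_id.split('_')[1]}",
                department=dep,
                consulted_texts=tuple(texts_by_physician[phys_id]),
                reply_text_lengths=tuple(int(x) for x in reply_lengths),
                voice_durations=tuple(round(float(x), 1) for x in voice_durations),
            )
        )

    return Corpus(complaints=complaints, physicians=physicians)


def generate_eval_fixture(
    n_physicians: int,
    n_above_text_baseline: int,
    n_above_voice_baseline: int,
    seed: int = 0,
) -> Corpus:
    """A physician pool in which exactly the requested counts beat the pool means.

    "Above" physicians all share one high constant reply length / voice
    duration and the rest one low constant, so the pool mean sits strictly
    between them. Having every physician above the mean is impossible and
    raises ``ConfigError``.
    """
    for n_above, what in ((n_above_text_baseline, "text"),
                          (n_above_voice_baseline, "voice")):
        if not 0 <= n_above <= n_physicians:
            raise ConfigError(f"n_above_{what} out of range")
        if n_above == n_physicians and n_physicians > 1:
            raise ConfigError(
                f"all {n_physicians} physicians cannot exceed their own pool mean ({what})"
            )
    rng = np.random.default_rng(seed)
    low_text, high_text = 20, 200
    low_voice, high_voice = 5.0, 40.0
    physicians = []
    complaints = []
    for i in range(n_physicians):
        phys_id = f"phys_{i + 1:03d}"
        t = high_text if i < n_above_text_baseline else low_text
        v = high_voice if i < n_above_voice_baseline else low_voice
        n_msgs = int(rng.integers(3, 8))
        text = f"tok{i} symptom complaint"
        physicians.append(
            PhysicianRecord(
                physician_id=phys_id,
                name=f"Physician {i + 1:03d}",
                department="dept_0",
                consulted_texts=(text,),
                reply_text_lengths=(t,) * n_msgs,
                voice_durations=(v,) * n_msgs,
            )
        )
        complaints.append(
            ComplaintRecord(
                patient_id=f"pat_{i + 1:05d}",
                text=text,
                disease="disease_0_0",
                department="dept_0",
                consulted_physician_id=phys_id,
            )
        )
    return Corpus(complaints=complaints, physicians=physicians)
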