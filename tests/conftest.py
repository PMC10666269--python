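import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxidna.ensemble import Frame, NucleobaseRecord, StepParameters, StrandEnsemble

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_frame(
    frame_id: int,
    sequence: str = "CTCT",
    dq=(0.40, 0.32, 0.16, 0.08),
    q_neutral=None,
    vie: float = 6.44,
    vae: float = 4.28,
    steps=None,
) -> Frame:
    """Handmade frame: q_cation = q_neutral + dq, default B-form-ish steps."""
    m = len(sequence)
    if q_neutral is None:
        q_neutral = [0.0] * m
    bases = tuple(
        NucleobaseRecord(i + 1, sequence[i], q_neutral[i], q_neutral[i] + dq[i]) for i in range(m)
    )
    if steps is None:
        steps = tuple(
            StepParameters(k + 1, 0.1 * k, -0.2, 3.4, 1.0, -2.0, 32.0 + k) for k in range(m - 1)
        )
    return Frame(frame_id=frame_id, bases=bases, vie=vie, vae=vae, steps=steps)


def make_ensemble(n_frames: int = 2, sequence: str = "CTCT", **kw) -> StrandEnsemble:
    frames = [make_frame(i + 1, sequence=sequence, **kw) for i in range(n_frames)]
    return StrandEnsemble("ss-test", sequence, frames)


def random_ensemble(rng: np.random.Generator, n_frames: int = 5, sequence: str = "ACGT") -> StrandEnsemble:
    m = len(sequence)
    frames = []
    for fid in range(1, n_frames + 1):
        dq = rng.dirichlet(np.full(m, 2.0))
        qn = rng.normal(0, 0.05, m)
        steps = tuple(
            StepParameters(
                k + 1,
                rng.normal(0, 0.8),
                rng.normal(0, 0.8),
                rng.normal(3.4, 0.4),
                rng.normal(0, 8),
                rng.normal(0, 8),
                rng.normal(30, 12),
            )
            for k in range(m - 1)
        )
        frames.append(
            Frame(
                frame_id=fid,
                bases=tuple(
                    NucleobaseRecord(i + 1, sequence[i], float(qn[i]), float(qn[i] + dq[i]))
                    for i in range(m)
                ),
                vie=float(rng.normal(6.5, 0.3)),
                vae=float(rng.normal(4.3, 0.3)),
                steps=steps,
            )
        )
    return StrandEnsemble("ss-random", sequence, frames)


@pytest.fixture
def small_ensemble() -> StrandEnsemble:
    return make_ensemble(n_frames=2)
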