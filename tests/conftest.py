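import pytest

from songsyntax import RunConfig, generate_study
from songsyntax.pipeline import compute_metrics_table, run_statistics
from songsyntax.types import BirdCorpus, Song, SyllableToken


def make_song(labels, start=0.0, dur=0.1, gap=0.05):
    """Helper: a timed song from a list of labels."""
    tokens = []
    t = start
    for lab in labels:
        tokens.append(SyllableToken(lab, round(t, 3), round(t + dur, 3)))
        t += dur + gap
    return Song(tuple(tokens))


def make_corpus(song_labels, bird_id="b1", sex="male", treatment="T", **kwargs):
    songs = []
    t = 0.0
    for labels in song_labels:
        songs.append(make_song(labels, start=t))
        t += len(labels) * 0.15 + 1.0
    return BirdCorpus(bird_id, sex, treatment, tuple(songs), **kwargs)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (15 males, 13 females, 30 songs each)."""
    return generate_study(seed=20240901)


@pytest.fixture(scope="session")
def study_metrics(default_study):
    """Per-bird metrics table of the default study."""
    config = RunConfig(input_path=".", input_kind="sequence_table", output_dir=".")
    table, log = compute_metrics_table(default_study, config)
    return table


@pytest.fixture(scope="session")
def study_statistics(study_metrics):
    config = RunConfig(input_path=".", input_kind="sequence_table", output_dir=".")
    return run_statistics(study_metrics, config)
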