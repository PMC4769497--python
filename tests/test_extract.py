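"""Extraction: per-type FASTQ/FASTA files, event tables, squiggle series."""

import pytest

from poremap.extract import (
    NoEventsError,
    events_tsv,
    extract_events,
    extract_fasta,
    extract_fastq,
    iter_source,
    squiggle_series,
)
from poremap.fast5 import read_fast5

from .test_fast5 import make_record


def parse_fastq_file(path):
    lines = path.read_text().splitlines()
    assert len(lines) % 4 == 0
    records = []
    for i in range(0, len(lines), 4):
        name, seq, plus, qual = lines[i : i + 4]
        assert name.startswith("@") and plus.startswith("+")
        assert len(seq) == len(qual)
        records.append((name[1:], seq, qual))
    return records


def test_extract_fastq_matches_ground_truth(small_dataset, tmp_path):
    folder, manifest, cfg = small_dataset
    counts = extract_fastq(folder, tmp_path)
    run_dir = tmp_path / cfg.run_id
    by_type = {"template": [], "complement": [], "2d": []}
    for m in sorted(manifest, key=lambda m: m.filename):
        for rt in m.read_types:
            by_type[rt].append(m.sequences[rt])
    token = {"template": "template", "complement": "complement", "2d": "2D"}
    for rt, seqs in by_type.items():
        path = run_dir / f"{token[rt]}.fastq"
        assert path.exists()
        records = parse_fastq_file(path)
        assert [seq for _, seq, _ in records] == seqs
        assert counts[cfg.run_id][rt] == len(seqs)


def test_extracted_fastq_bytes_equal_embedded_text(small_dataset, tmp_path):
    folder, manifest, cfg = small_dataset
    extract_fastq(folder, tmp_path)
    embedded = {"template": [], "complement": [], "2d": []}
    for key, blob in iter_source(folder):
        record = read_fast5(blob)
        for rt, read in record.reads.items():
            embedded[rt].append(read.fastq_text)
    token = {"template": "template", "complement": "complement", "2d": "2D"}
    for rt, texts in embedded.items():
        assert (tmp_path / cfg.run_id / f"{token[rt]}.fastq").read_text() == "".join(
            texts
        )


def test_absent_types_yield_empty_files(tmp_path):
    from poremap.fast5 import write_fast5

    src = tmp_path / "src"
    src.mkdir()
    write_fast5(make_record(("template",)), src / "only_t.fast5")
    out = tmp_path / "out"
    counts = extract_fastq(src, out)
    run_dir = out / "run_x"
    assert (run_dir / "complement.fastq").stat().st_size == 0
    assert (run_dir / "2D.fastq").stat().st_size == 0
    assert counts["run_x"] == {"template": 1, "complement": 0, "2d": 0}


def test_fasta_is_projection_of_fastq(small_dataset, tmp_path):
    folder, manifest, cfg = small_dataset
    fq_counts = extract_fastq(folder, tmp_path / "fq")
    fa_counts = extract_fasta(folder, tmp_path / "fa")
    assert fq_counts == fa_counts
    fa = (tmp_path / "fa" / cfg.run_id / "template.fasta").read_text().splitlines()
    fq = (tmp_path / "fq" / cfg.run_id / "template.fastq").read_text().splitlines()
    assert len(fa) * 2 == len(fq)
    for i in range(0, len(fa), 2):
        assert fa[i].startswith(">")
        assert fa[i][1:] == fq[2 * i][1:]   # header = read name
        assert fa[i + 1] == fq[2 * i + 1]   # same sequence


def test_extraction_from_archive_equals_folder(small_dataset, tmp_path):
    from poremap.archive import import_folder

    folder, _, cfg = small_dataset
    import_folder(folder, tmp_path / "arch")
    extract_fastq(folder, tmp_path / "from_folder")
    extract_fastq(tmp_path / "arch", tmp_path / "from_archive")
    for rt in ("template", "complement", "2D"):
        a = (tmp_path / "from_folder" / cfg.run_id / f"{rt}.fastq").read_bytes()
        b = (tmp_path / "from_archive" / cfg.run_id / f"{rt}.fastq").read_bytes()
        assert a == b


def test_events_tsv_round_trip(tmp_path):
    record = make_record(("template",), n_events=250)
    tsv = events_tsv(record, "template")
    lines = tsv.strip().split("\n")
    assert len(lines) == 251
    assert lines[0].split("\t") == [
        "mean", "stdv", "start", "length", "model_state", "move",
    ]
    for line, event in zip(lines[1:], record.events["template"]):
        mean, stdv, start, length, state, move = line.split("\t")
        assert float(mean) == pytest.approx(event.mean, rel=1e-5)
        assert float(start) == pytest.approx(event.start, rel=1e-5)
        assert state == event.model_state
        assert int(move) == event.move


def test_extract_events_missing_key(small_dataset):
    folder, _, _ = small_dataset
    with pytest.raises(KeyError, match="nope.fast5"):
        extract_events(folder, "nope.fast5", "template")


def test_extract_events_from_archive(small_dataset, tmp_path):
    from poremap.archive import import_folder

    folder, manifest, _ = small_dataset
    import_folder(folder, tmp_path / "arch")
    key = manifest[0].filename
    assert extract_events(tmp_path / "arch", key, "template") == extract_events(
        folder, key, "template"
    )


def test_no_events_error():
    record = make_record(("template",))
    with pytest.raises(NoEventsError):
        events_tsv(record, "complement")
    with pytest.raises(NoEventsError):
        squiggle_series(record, "2d")


def test_squiggle_series_step_function():
    record = make_record(("template",), n_events=1)
    record.events["template"] = [record.events["template"][0]]
    e = record.events["template"][0]
    points = squiggle_series(record, "template")
    assert [(p.time, p.level) for p in points] == [
        (e.start, e.mean),
        (e.start + e.length, e.mean),
    ]


def test_squiggle_times_non_decreasing_and_span():
    record = make_record(("template",), n_events=40)
    events = record.events["template"]
    points = squiggle_series(record, "template")
    assert len(points) == 2 * len(events)
    times = [p.time for p in points]
    assert times == sorted(times)
    span = points[-1].time - points[0].time
    expected = events[-1].start + events[-1].length - events[0].start
    assert span == pytest.approx(expected)
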