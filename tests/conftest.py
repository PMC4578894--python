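from hypothesis import HealthCheck, settings

from semascaf.blast_io import HomologyEdge

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_edge(
    query: str,
    subject: str,
    evalue: float = 1e-10,
    bit_score: float = 100.0,
    alignment_length: int = 100,
) -> HomologyEdge:
    """Edge with plausible filler alignment statistics."""
    return HomologyEdge(
        query_id=query,
        subject_id=subject,
        percent_identity=95.0,
        alignment_length=alignment_length,
        mismatches=5,
        gap_opens=0,
        q_start=1,
        q_end=alignment_length,
        s_start=1,
        s_end=alignment_length,
        evalue=evalue,
        bit_score=bit_score,
    )
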