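"""Pytest anchor; keeps the tests directory importable (shared _toys helpers)."""
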