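"""Audit trail: one structured entry per modification of a record.

The trail makes the curation recoverable — every value-altering step records
the sample, the pipeline stage, the field or taxon touched, and the value
before and after, so any record can be traced back to its source state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field


@dataclass
class AuditLog:
    entries: list = field(default_factory=list)

    def record(self, sample_id: str, stage: str, target: str,
               before, after, rule: str = "") -> None:
        self.entries.append({
            "sample_id": sample_id,
            "stage": stage,
            "target": target,
            "before": before,
            "after": after,
            "rule": rule,
        })

    def for_sample(self, sample_id: str) -> list:
        return [e for e in self.entries if e["sample_id"] == sample_id]

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for entry in self.entries:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "AuditLog":
        log = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    log.entries.append(json.loads(line))
        return log
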