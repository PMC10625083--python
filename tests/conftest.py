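from datetime import datetime

import pytest

from chatmood.chatlog_io import ChatRecord, map_region


@pytest.fixture
def make_record():
    """Factory for valid ChatRecords with compact overrides."""

    def _make(uid="u1", user="alice", country="Canada", hour=12,
              text="i am sad today", bot="oh no"):
        return ChatRecord(
            utterance_id=uid, user_id=user, country=country,
            region=map_region(country),
            timestamp=datetime(2018, 6, 1, hour, 30),
            user_text=text, bot_text=bot,
        )

    return _make
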