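"""Message channels: console and watched drop-folder.

The drop-folder channel treats each UTF-8 text file in a directory as one
incoming message (lexicographic filename order); replies are written next
to the message with a ``.reply`` suffix and consumed messages are renamed
with a ``.read`` suffix so they are only delivered once.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

READ_SUFFIX = ".read"
REPLY_SUFFIX = ".reply"


class Channel:
    """Plain send/receive text transport."""

    name = "base"

    def send(self, text: str) -> None:
        raise NotImplementedError

    def receive(self) -> Optional[str]:
        """Next pending message, or ``None``."""
        raise NotImplementedError


class ConsoleChannel(Channel):
    name = "console"

    def __init__(self):
        self._inbox: List[str] = []

    def feed(self, text: str) -> None:
        """Queue a message as if typed on the console (used by tests/CLI)."""
        self._inbox.append(text)

    def send(self, text: str) -> None:
        print(text)

    def receive(self) -> Optional[str]:
        return self._inbox.pop(0) if self._inbox else None


class DropFolderChannel(Channel):
    name = "dropfolder"

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self._last_received: Optional[Path] = None

    def _pending(self) -> List[Path]:
        return sorted(
            p for p in self.directory.iterdir()
            if p.is_file()
            and not p.name.endswith(READ_SUFFIX)
            and not p.name.endswith(REPLY_SUFFIX)
        )

    def receive(self) -> Optional[str]:
        pending = self._pending()
        if not pending:
            return None
        path = pending[0]
        text = path.read_text(encoding="utf-8")
        read_path = path.with_name(path.name + READ_SUFFIX)
        path.rename(read_path)
        self._last_received = read_path
        return text

    def send(self, text: str) -> None:
        if self._last_received is not None:
            base = self._last_received.name[: -len(READ_SUFFIX)]
            out = self.directory / (base + REPLY_SUFFIX)
        else:
            out = self.directory / ("broadcast" + REPLY_SUFFIX)
        out.write_text(text, encoding="utf-8")


def make_channel(name: str, directory: Optional[str] = None) -> Channel:
    if name == "console":
        return ConsoleChannel()
    if name == "dropfolder":
        return DropFolderChannel(directory or "messages")
    from .errors import ConfigurationError
    raise ConfigurationError(f"unknown channel {name!r}")
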