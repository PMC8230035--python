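# Synthetic helpline registry shipped for testing and demonstration.
#
# The operational-helpline criterion (P2) verifies help-seeking information
# against a local registry file; deployments should replace this file with a
# curated, periodically re-verified list for their region. Numbers below are
# placeholders, not live services.
version: "2026.09-1"
entries:
  - name: Sneha Suicide Prevention Centre
    phone: 044-24640050
  - name: iCALL Helpline
    phone: 022-25521111
  - name: AASRA Helpline
    phone: 022-27546669
  - name: Kiran Helpline
    phone: 1800-599-0019
  - name: Vandrevala Foundation Helpline
    phone: 1860-266-2345
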