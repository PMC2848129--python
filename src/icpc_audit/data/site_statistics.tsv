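# Published per-site figures from the 12-site Norwegian primary-care material
# (study window opens 1992-01-02): collection period, patient and problem-event
# counts, and the per-site audit failure rates (percent of the site's events).
site	first_event	last_event	patients	problem_events	pct_missing	pct_code_mismatch	pct_text_mismatch
Centre 1	1992-01-06	2007-12-17	9973	304342	7.2	12.7	49.5
Centre 2	1992-01-02	2008-01-15	11469	334232	4.6	2.3	70.0
Centre 3	1992-01-02	2007-12-21	12179	208139	0	0.3	69.2
GP 1	1992-01-02	2007-05-04	3758	109129	3.8	0.6	6.7
GP 2	1992-01-01	2008-01-31	1337	17925	5.3	6.5	24.8
GP 3	2002-10-08	2007-05-01	3809	10512	0	5.0	26.4
GP 4	1992-01-02	2007-09-11	7800	108394	36.1	0.7	25.1
GP 5	1992-01-02	2007-09-03	5010	137635	2.0	0.6	15.4
GP 6	2004-12-08	2006-01-17	1140	7971	0	2.3	44.2
GP 7	1992-01-03	1999-12-28	6025	30500	6.7	2.6	77.7
GP 8	1992-01-06	1999-12-03	7077	71004	3.9	5.6	73.6
GP 9	1992-10-09	2008-01-28	6374	160811	2.6	2.8	82.1
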