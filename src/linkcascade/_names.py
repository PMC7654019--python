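"""Bundled name and municipality-code lists for the synthetic generator.

Small fixture lists of common Brazilian given names and surnames (the real
frequency tables behind national registries are not redistributable), plus a
deterministic list of municipality codes in the 7-digit IBGE layout: two
state digits drawn from the 27 real state prefixes, four municipality digits
and one check digit.
"""

from __future__ import annotations

import numpy as np

FEMALE_GIVEN = [
    "MARIA", "ANA", "FRANCISCA", "ANTONIA", "ADRIANA", "JULIANA", "MARCIA",
    "FERNANDA", "PATRICIA", "ALINE", "SANDRA", "CAMILA", "AMANDA", "BRUNA",
    "JESSICA", "LETICIA", "JULIA", "LUCIANA", "VANESSA", "MARIANA",
    "GABRIELA", "VERA", "VITORIA", "LARISSA", "CLAUDIA", "BEATRIZ", "LUZIA",
    "RITA", "SONIA", "RENATA", "ELIANE", "CRISTIANE", "ANGELA", "FATIMA",
    "ROSANGELA", "SIMONE", "TEREZINHA", "DANIELA", "RAIMUNDA", "SOLANGE",
    "JOSEFA", "MARINA", "IRACEMA", "DEBORA", "REGINA", "ALICE", "HELENA",
    "LAURA", "ISABEL", "CECILIA", "CLARA", "ROSA", "CARLA", "PAULA",
    "TATIANE", "PRISCILA", "SABRINA", "MICHELE", "KELLY", "VIVIANE",
    "ELAINE", "CRISTINA", "SUELI", "APARECIDA", "NEUSA", "IVONE", "MARLENE",
    "ZILDA", "NAIR", "DALVA", "EDNA", "GILDA", "IVETE", "LOURDES", "NADIA",
    "ODETE", "ROSELI", "TANIA", "VALERIA", "WILMA", "CAROLINA", "EMILIA",
    "ESTELA", "FLAVIA", "GRAZIELA", "INES", "JANAINA", "KARINA", "LIDIA",
    "MIRIAM", "NATALIA", "OLIVIA", "PAMELA", "RAQUEL", "SILVIA", "TALITA",
    "URSULA", "VANIA", "YASMIN", "ZELIA",
]

MALE_GIVEN = [
    "JOSE", "JOAO", "ANTONIO", "FRANCISCO", "CARLOS", "PAULO", "PEDRO",
    "LUCAS", "LUIZ", "MARCOS", "LUIS", "GABRIEL", "RAFAEL", "DANIEL",
    "MARCELO", "BRUNO", "EDUARDO", "FELIPE", "RAIMUNDO", "RODRIGO",
    "MANOEL", "MATEUS", "ANDRE", "FERNANDO", "FABIO", "LEONARDO",
    "GUSTAVO", "GUILHERME", "LEANDRO", "TIAGO", "SEBASTIAO", "ALEXANDRE",
    "MARCIO", "RICARDO", "DIEGO", "EDSON", "VITOR", "ROBERTO", "SERGIO",
    "CLAUDIO", "GERALDO", "ADRIANO", "JORGE", "DOUGLAS", "ALEX", "RENATO",
    "JULIO", "CESAR", "VINICIUS", "MAURICIO", "GILBERTO", "SAMUEL",
    "WELLINGTON", "JAIR", "OSVALDO", "NELSON", "WILSON", "AILTON",
    "BENEDITO", "CICERO", "DOMINGOS", "ELIAS", "EVERTON", "FLAVIO",
    "GEORGE", "HELIO", "IGOR", "IVAN", "JACKSON", "KLEBER", "LAERCIO",
    "MILTON", "NILTON", "ORLANDO", "OTAVIO", "PABLO", "QUIRINO", "RAUL",
    "SANDRO", "TADEU", "UBIRAJARA", "VALDIR", "WAGNER", "XAVIER", "YURI",
    "ZACARIAS", "ADEMIR", "BENTO", "CRISTIANO", "DAVI", "ERNESTO",
    "FAUSTO", "GENIVALDO", "HUGO", "ISAIAS", "JONAS", "LAURO", "MOACIR",
    "NORBERTO", "OSCAR",
]

SURNAMES = [
    "SILVA", "SANTOS", "OLIVEIRA", "SOUZA", "RODRIGUES", "FERREIRA",
    "ALVES", "PEREIRA", "LIMA", "GOMES", "COSTA", "RIBEIRO", "MARTINS",
    "CARVALHO", "ALMEIDA", "LOPES", "SOARES", "FERNANDES", "VIEIRA",
    "BARBOSA", "ROCHA", "DIAS", "NASCIMENTO", "ANDRADE", "MOREIRA",
    "NUNES", "MARQUES", "MACHADO", "MENDES", "FREITAS", "CARDOSO",
    "RAMOS", "GONCALVES", "SANTANA", "TEIXEIRA", "ARAUJO", "PINTO",
    "CORREIA", "MONTEIRO", "MOURA", "CAVALCANTE", "BATISTA", "REIS",
    "MORAES", "CASTRO", "CAMPOS", "MIRANDA", "AZEVEDO", "CUNHA", "DUARTE",
    "BRITO", "BARROS", "MELO", "NOGUEIRA", "SALES", "MEDEIROS", "FARIAS",
    "TAVARES", "AGUIAR", "SIQUEIRA", "BEZERRA", "BORGES", "CALDAS",
    "DANTAS", "ESTEVES", "FONSECA", "GUIMARAES", "HENRIQUES", "IGLESIAS",
    "JESUS", "LACERDA", "MAGALHAES", "NEVES", "OTERO", "PACHECO",
    "QUEIROZ", "REZENDE", "SAMPAIO", "TELES", "URBANO", "VALENTE",
    "XIMENES", "ZANETTI", "AMARAL", "BRANDAO", "COUTINHO", "DOMINGUES",
    "EVANGELISTA", "FIGUEIREDO", "GARCIA", "HOLANDA", "ITAPARICA",
    "JARDIM", "KRUGER", "LEAL", "MAIA", "NONATO", "OURIQUES", "PAIVA",
    "QUADROS", "ROSAS", "SERPA", "TORRES", "UCHOA", "VASCONCELOS",
    "WANDERLEY", "XAVIER", "ZAGALO", "ABREU", "BITTENCOURT", "CHAVES",
    "DORNELES", "ESPINDOLA", "FROTA", "GUERRA", "HORTA", "INOJOSA",
    "JUSTINO", "KLEIN", "LUSTOSA",
]

#: the 27 real two-digit state prefixes of the IBGE municipality code
STATE_PREFIXES = [
    "11", "12", "13", "14", "15", "16", "17", "21", "22", "23", "24", "25",
    "26", "27", "28", "29", "31", "32", "33", "35", "41", "42", "43", "50",
    "51", "52", "53",
]


def _make_ibge_codes(n_per_state: int = 4, seed: int = 20201109) -> list[str]:
    rng = np.random.default_rng(seed)
    codes = []
    for prefix in STATE_PREFIXES:
        bodies = rng.choice(9999, size=n_per_state, replace=False)
        for body in bodies:
            check = rng.integers(0, 10)
            codes.append(f"{prefix}{int(body):04d}{int(check)}")
    return sorted(codes)


#: bundled municipality-code fixture (IBGE 7-digit layout, 108 codes)
IBGE_CODES = _make_ibge_codes()
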