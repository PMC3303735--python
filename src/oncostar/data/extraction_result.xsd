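<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the report-extraction output document.  Hormone-receptor
     elements hold either a percent in [0,100] or a qualitative status. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="percentType">
    <xs:restriction base="xs:decimal">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="100"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="statusType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="positive"/>
      <xs:enumeration value="negative"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="receptorType">
    <xs:union memberTypes="percentType statusType"/>
  </xs:simpleType>

  <xs:simpleType name="isoDateOrEmpty">
    <xs:restriction base="xs:string">
      <xs:pattern value="(\d{4}-\d{2}-\d{2})?"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="reportType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="histological"/>
      <xs:enumeration value="cytological"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="herScoreType">
    <xs:restriction base="xs:integer">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="3"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="gradeType">
    <xs:restriction base="xs:integer">
      <xs:minInclusive value="1"/>
      <xs:maxInclusive value="3"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="tnmType">
    <xs:restriction base="xs:string">
      <xs:pattern value="(c|p|yp)?T(X|0|is|1|1a|1b|1c|2|3|4|4a|4b|4c|4d) N(X|0|1|1a|2|2a|3) M(X|0|1)"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="document">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="name" type="xs:string"/>
        <xs:element name="date" type="isoDateOrEmpty"/>
        <xs:element name="type" type="reportType"/>
        <xs:element name="number" type="xs:string" minOccurs="0"/>
        <xs:element name="estrogens_receptors" type="receptorType" minOccurs="0"/>
        <xs:element name="progesterone_receptors" type="receptorType" minOccurs="0"/>
        <xs:element name="Ki67" type="percentType" minOccurs="0"/>
        <xs:element name="c-erb_B2" type="herScoreType" minOccurs="0"/>
        <xs:element name="grade" type="gradeType" minOccurs="0"/>
        <xs:element name="state" type="tnmType" minOccurs="0"/>
        <xs:element name="snomed" minOccurs="0">
          <xs:complexType>
            <xs:sequence minOccurs="0" maxOccurs="unbounded">
              <xs:element name="code" type="xs:string"/>
              <xs:element name="name" type="xs:string"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
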